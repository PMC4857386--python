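"""Independent naive re-scan oracle for peptide-ladder merging.

Works on plain (start, end, n_block, c_block, support) tuples anchored on a
single precursor string, recomputes *all* pairwise overlaps from scratch at
every iteration, and applies the merge rules directly from their
definitions.  Deliberately shares no code with peptilap.assembly.
"""

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class Pep:
    start: int
    end: int
    n_block: bool
    c_block: bool
    support: frozenset

    @property
    def ident(self):
        return (self.start, self.end, self.n_block, self.c_block)


def shared_residues(a: Pep, b: Pep):
    """Number of shared positions, or None when a merge is not allowed."""
    positions = set(range(a.start, a.end + 1)) & set(range(b.start, b.end + 1))
    if len(positions) < 2:
        return None
    for x, y in ((a, b), (b, a)):
        if x.n_block and y.start < x.start:
            return None
        if x.c_block and y.end > x.end:
            return None
    return len(positions)


def naive_assemble(peps: list[Pep]) -> set:
    """Literal greedy loop: rescan every pair, merge the largest allowed
    overlap (ties: smallest merged interval, then smallest pair identity),
    repeat to fixpoint.  Returns the set of final peptide identities with
    their support sets."""
    current = list(peps)
    while True:
        best = None
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                a, b = current[i], current[j]
                s = shared_residues(a, b)
                if s is None:
                    continue
                merged_interval = (min(a.start, b.start), max(a.end, b.end))
                lo, hi = sorted((a.ident, b.ident))
                rank = (-s, merged_interval, lo, hi)
                if best is None or rank < best[0]:
                    best = (rank, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = current[i], current[j]
        merged = Pep(
            start=min(a.start, b.start),
            end=max(a.end, b.end),
            n_block=(a.n_block and a.start <= b.start) or (b.n_block and b.start <= a.start),
            c_block=(a.c_block and a.end >= b.end) or (b.c_block and b.end >= a.end),
            support=a.support | b.support,
        )
        current = [p for k, p in enumerate(current) if k not in (i, j)]
        # a merge landing on an existing identity collapses into it
        absorbed = False
        for k, p in enumerate(current):
            if p.ident == merged.ident:
                current[k] = replace(p, support=p.support | merged.support)
                absorbed = True
                break
        if not absorbed:
            current.append(merged)
    return {(p.start, p.end, p.n_block, p.c_block, p.support) for p in current}


def random_instance(rng, precursor_len: int, n_peps: int, block_prob: float = 0.2):
    """Random unique peptide set over one toy precursor."""
    peps = {}
    for i in range(n_peps):
        start = int(rng.integers(1, precursor_len - 2))
        length = int(rng.integers(2, min(15, precursor_len - start + 1) + 1))
        end = start + length - 1
        n_block = bool(rng.random() < block_prob)
        c_block = bool(rng.random() < block_prob)
        key = (start, end, n_block, c_block)
        if key in peps:
            peps[key] = replace(peps[key], support=peps[key].support | {i})
        else:
            peps[key] = Pep(start, end, n_block, c_block, frozenset({i}))
    return list(peps.values())
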