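"""Fragment-based average nucleotide identity and species delimitation.

A query genome is cut into non-overlapping ~1 kb fragments; each fragment is
seeded onto the reference by exact shared k-mers (both strands), aligned
globally against the best candidate window, and the ANI estimate is the mean
percent identity of the mapped fragments. The ANI matrix feeds a threshold
clustering (connected components of the >= 95% graph are the species
blocks) and a quality-score dereplication that keeps one representative per
cluster of near-identical genomes.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np

from .io import GenomeMetadata

__all__ = [
    "ANIMatrix",
    "SpeciesPartition",
    "fragment_ani",
    "ani_matrix",
    "species_partition",
    "dereplicate",
]

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass
class ANIMatrix:
    """Symmetrised pairwise ANI estimates (percent); NaN when unmapped."""

    genomes: list[str]
    ani: np.ndarray
    frac_mapped: np.ndarray

    def value(self, a: str, b: str) -> float:
        i, j = self.genomes.index(a), self.genomes.index(b)
        return float(self.ani[i, j])


@dataclass
class SpeciesPartition:
    """Genome blocks produced by threshold clustering of an ANI matrix."""

    blocks: list[frozenset[str]]
    threshold: float

    def block_of(self, genome: str) -> frozenset[str]:
        for b in self.blocks:
            if genome in b:
                return b
        raise KeyError(genome)

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.blocks)


class _RefIndex:
    """Exact k-mer positions of a reference genome (forward strand)."""

    def __init__(self, seq: str, k: int) -> None:
        self.seq = seq
        self.k = k
        index: dict[str, list[int]] = defaultdict(list)
        for p in range(len(seq) - k + 1):
            index[seq[p : p + k]].append(p)
        self.index = index


def _map_fragment(
    frag: str, ref: _RefIndex, min_frag_cov: float
) -> float | None:
    """Percent identity of the best mapping of one fragment, or None."""
    k = ref.k
    flen = len(frag)
    pad = max(30, flen // 6)
    best = None
    for strand_seq in (frag, _revcomp(frag)):
        positions = range(0, max(1, flen - k + 1), k)
        diagonals: Counter[int] = Counter()
        for off in positions:
            for p in ref.index.get(strand_seq[off : off + k], ()):
                diagonals[p - off] += 1
        if not diagonals:
            # retry with every k-mer before giving up on this strand
            for off in range(0, max(1, flen - k + 1)):
                for p in ref.index.get(strand_seq[off : off + k], ()):
                    diagonals[p - off] += 1
        if not diagonals:
            continue
        diag, _votes = max(diagonals.items(), key=lambda t: (t[1], -t[0]))
        start = max(0, diag - pad)
        end = min(len(ref.seq), diag + flen + pad)
        window = ref.seq[start:end]
        if len(window) < min_frag_cov * flen:
            continue
        res = edlib.align(strand_seq, window, mode="HW", task="distance")
        dist = res["editDistance"]
        if dist < 0:
            continue
        identity = 1.0 - dist / flen
        if best is None or identity > best:
            best = identity
    return best


def fragment_ani(
    query: str,
    reference: str,
    frag_len: int = 1000,
    k: int = 16,
    min_frag_cov: float = 0.7,
) -> tuple[float | None, float]:
    """One-directional fragment ANI of ``query`` against ``reference``.

    Returns ``(ani_percent, fraction_of_fragments_mapped)``; ANI is None
    when no fragment maps. Genomes shorter than one fragment are compared
    as a single fragment (with a warning).
    """
    if not query or not reference:
        raise ValueError("empty genome sequence")
    if len(query) < frag_len:
        warnings.warn("genome shorter than one fragment; single-fragment mode",
                      stacklevel=2)
        fragments = [query]
    else:
        fragments = [
            query[i : i + frag_len]
            for i in range(0, len(query) - frag_len + 1, frag_len)
        ]
    ref = reference if isinstance(reference, _RefIndex) else _RefIndex(reference, k)
    identities = []
    for frag in fragments:
        ident = _map_fragment(frag, ref, min_frag_cov)
        if ident is not None:
            identities.append(ident)
    if not identities:
        return None, 0.0
    return 100.0 * float(np.mean(identities)), len(identities) / len(fragments)


def ani_matrix(
    genomes: dict[str, str],
    frag_len: int = 1000,
    k: int = 16,
    min_frag_cov: float = 0.7,
) -> ANIMatrix:
    """All-ordered-pairs fragment ANI, symmetrised by the mean of the two
    directions (or the single defined direction)."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    names = list(genomes)
    n = len(names)
    indexes = {g: _RefIndex(genomes[g], k) for g in names}
    directional = np.full((n, n), np.nan)
    frac = np.zeros((n, n))
    for i, qi in enumerate(names):
        for j, rj in enumerate(names):
            if i == j:
                directional[i, j] = 100.0
                frac[i, j] = 1.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ani, fm = fragment_ani(
                    genomes[qi], indexes[rj], frag_len=frag_len, k=k,
                    min_frag_cov=min_frag_cov,
                )
            if ani is not None:
                directional[i, j] = ani
            frac[i, j] = fm
    sym = np.full((n, n), np.nan)
    for i in range(n):
        sym[i, i] = 100.0
        for j in range(i + 1, n):
            vals = [v for v in (directional[i, j], directional[j, i]) if not np.isnan(v)]
            if vals:
                sym[i, j] = sym[j, i] = float(np.mean(vals))
    fsym = (frac + frac.T) / 2
    return ANIMatrix(genomes=names, ani=sym, frac_mapped=fsym)


def species_partition(m: ANIMatrix, threshold: float = 95.0) -> SpeciesPartition:
    """Connected components of the graph with an edge wherever symmetrised
    ANI >= ``threshold``."""
    n = len(m.genomes)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            v = m.ani[i, j]
            if not np.isnan(v) and v >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, set[str]] = defaultdict(set)
    for i, g in enumerate(m.genomes):
        groups[find(i)].add(g)
    blocks = [frozenset(v) for _, v in sorted(groups.items())]
    return SpeciesPartition(blocks=blocks, threshold=threshold)


def derep_score(meta: GenomeMetadata) -> float:
    """Quality score for representative selection:
    completeness - 5 x contamination + 0.5 x log10(N50)."""
    return meta.completeness - 5.0 * meta.contamination + 0.5 * np.log10(meta.n50)


def dereplicate(
    m: ANIMatrix,
    meta: list[GenomeMetadata],
    threshold: float = 99.0,
) -> list[str]:
    """Single-linkage clusters at ``threshold`` ANI; keeps the genome with
    the highest quality score per cluster (ties: lexicographic accession).
    Returns representatives in the matrix's genome order."""
    by_acc = {mm.accession: mm for mm in meta}
    missing = [g for g in m.genomes if g not in by_acc]
    if missing:
        raise ValueError(f"no metadata for genomes {missing}")
    clusters = species_partition(m, threshold).blocks
    reps = []
    for block in clusters:
        best = sorted(block, key=lambda g: (-derep_score(by_acc[g]), g))[0]
        reps.append(best)
    order = {g: i for i, g in enumerate(m.genomes)}
    return sorted(reps, key=order.get)
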