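"""Multiple alignment, conserved-site selection and supermatrix assembly.

Gene families are aligned progressively (pairwise global alignments guided
by a UPGMA tree on k-mer distances), conserved sites are selected by
per-column entropy and gap-fraction cutoffs, protein alignments can be
back-translated onto their coding sequences, and per-gene alignments are
concatenated into a supermatrix over a fixed taxon list with explicit
missing-state accounting: taxa absent from a gene are padded with ``?``,
which is counted as missing, while alignment gaps ``-`` are not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import FormatError, MolType, SequenceRecord

__all__ = [
    "MultipleAlignment",
    "Supermatrix",
    "align_og",
    "trim_alignment",
    "back_translate",
    "concat_supermatrix",
    "codon_position_mask",
    "write_partition_file",
]

_GAPLIKE = "-?"


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by taxon (insertion order preserved)."""

    rows: dict[str, str]
    moltype: MolType

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    def as_array(self) -> np.ndarray:
        """Rows as a 2-D byte array (taxon order preserved)."""
        return np.frombuffer(
            "".join(self.rows.values()).encode(), dtype=np.uint8
        ).reshape(len(self.rows), self.length)


@dataclass
class Supermatrix:
    """Concatenated gene alignments over a fixed taxon list.

    ``partitions`` are half-open 0-based ``(og_id, start, end)`` spans that
    tile ``[0, length)``; ``missing_fraction`` is the share of ``?`` cells.
    """

    taxa: list[str]
    matrix: dict[str, str]
    partitions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.matrix.values()}
        if len(lengths) > 1:
            raise ValueError("ragged supermatrix")
        pos = 0
        for og, start, end in self.partitions:
            if start != pos or end < start:
                raise ValueError(f"partitions do not tile the matrix at {og}")
            pos = end
        if self.matrix and pos != self.length:
            raise ValueError("partitions do not cover the matrix")

    @property
    def length(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0

    @property
    def missing_fraction(self) -> float:
        total = len(self.taxa) * self.length
        if total == 0:
            return 0.0
        return sum(row.count("?") for row in self.matrix.values()) / total

    def as_alignment(self, moltype: MolType) -> MultipleAlignment:
        return MultipleAlignment(dict(self.matrix), moltype)


# ---------------------------------------------------------------------------
# progressive alignment


def _make_aligner(moltype: MolType) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if moltype is MolType.PROTEIN:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -6.0
        aligner.extend_gap_score = -1.0
    return aligner


def _kmer_distance_matrix(seqs: list[str], k: int = 3) -> np.ndarray:
    sets = [set(s[i : i + k] for i in range(max(1, len(s) - k + 1))) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j])) or 1
            d[i, j] = d[j, i] = 1.0 - len(sets[i] & sets[j]) / denom
    return d


def _consensus(profile: list[str], moltype: MolType) -> str:
    """Majority residue per column, gaps ignored; ties broken lexically."""
    fallback = "X" if moltype is MolType.PROTEIN else "N"
    cols = len(profile[0])
    arr = np.frombuffer("".join(profile).encode(), dtype=np.uint8).reshape(
        len(profile), cols
    )
    out = bytearray()
    gap = ord("-")
    qmark = ord("?")
    for c in range(cols):
        col = arr[:, c]
        col = col[(col != gap) & (col != qmark)]
        if col.size == 0:
            out.append(ord(fallback))
        else:
            vals, counts = np.unique(col, return_counts=True)
            out.append(int(vals[np.argmax(counts)]))  # np.unique sorts: ties lexical
    return bytes(out).decode()


def _project_gaps(aligned_consensus: str, profile: list[str]) -> list[str]:
    """Insert the gap columns of an aligned consensus into every profile row."""
    out_rows = ["" for _ in profile]
    pos = 0
    chunks: list[list[str]] = [[] for _ in profile]
    for ch in aligned_consensus:
        if ch == "-":
            for r in range(len(profile)):
                chunks[r].append("-")
        else:
            for r in range(len(profile)):
                chunks[r].append(profile[r][pos])
            pos += 1
    return ["".join(c) for c in chunks]


def align_og(seqs: list[SequenceRecord]) -> MultipleAlignment:
    """Progressive multiple alignment of a gene family.

    Pairwise steps use affine-gap global alignment (BLOSUM62 for protein,
    +1/-1 for DNA); the merge order follows a UPGMA tree built on k-mer
    distances; profiles are merged by aligning their column consensuses.
    Deterministic: ties in the guide tree and in the pairwise DP are resolved
    by input order and by Biopython's canonical first-reported alignment.
    """
    if len(seqs) < 2:
        raise ValueError("align_og requires at least 2 sequences")
    moltypes = {s.moltype for s in seqs}
    if len(moltypes) != 1:
        raise ValueError("mixed molecule types in one family")
    moltype = seqs[0].moltype
    aligner = _make_aligner(moltype)

    if len({s.seq for s in seqs}) == 1:
        return MultipleAlignment({s.id: s.seq for s in seqs}, moltype)

    d = _kmer_distance_matrix([s.seq for s in seqs])
    merges = linkage(squareform(d, checks=False), method="average")

    # cluster id -> (labels, gapped rows)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([s.id], [s.seq]) for i, s in enumerate(seqs)
    }
    n = len(seqs)
    for step, (a, b, _dist, _cnt) in enumerate(merges):
        la, pa = clusters.pop(int(a))
        lb, pb = clusters.pop(int(b))
        ca, cb = _consensus(pa, moltype), _consensus(pb, moltype)
        best = aligner.align(ca, cb)[0]
        aligned_a, aligned_b = str(best[0]), str(best[1])
        pa = _project_gaps(aligned_a, pa)
        pb = _project_gaps(aligned_b, pb)
        clusters[n + step] = (la + lb, pa + pb)
    labels, rows = clusters.popitem()[1]
    order = {s.id: i for i, s in enumerate(seqs)}
    pairs = sorted(zip(labels, rows), key=lambda t: order[t[0]])
    return MultipleAlignment(dict(pairs), moltype)


# ---------------------------------------------------------------------------
# conserved-site selection


def column_entropy(column: str, moltype: MolType) -> float:
    """Normalised Shannon entropy of a column's non-gap residues.

    Base-2 entropy divided by log2 of the alphabet size (20 for protein,
    4 for DNA); an all-gap or single-residue column scores 0.
    """
    residues = [c for c in column if c not in _GAPLIKE]
    if not residues:
        return 0.0
    _, counts = np.unique(residues, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log2(p)).sum())
    norm = math.log2(20 if moltype is MolType.PROTEIN else 4)
    return h / norm


def trim_alignment(
    aln: MultipleAlignment,
    entropy_cutoff: float = 0.5,
    gap_cutoff: float = 0.2,
) -> MultipleAlignment:
    """Keep columns with gap fraction <= ``gap_cutoff`` and normalised
    entropy <= ``entropy_cutoff`` (both boundaries inclusive); order is
    preserved and the operation is idempotent."""
    arr = aln.as_array()
    n_rows, n_cols = arr.shape
    gap_mask = (arr == ord("-")) | (arr == ord("?"))
    gap_frac = gap_mask.sum(axis=0) / n_rows
    keep: list[int] = []
    cols = np.ascontiguousarray(arr.T)
    for c in range(n_cols):
        if gap_frac[c] > gap_cutoff:
            continue
        column = cols[c].tobytes().decode()
        if column_entropy(column, aln.moltype) <= entropy_cutoff:
            keep.append(c)
    if not keep:
        warnings.warn("trimming removed every column", stacklevel=2)
        return MultipleAlignment({t: "" for t in aln.taxa}, aln.moltype)
    idx = np.array(keep)
    rows = {
        t: arr[i, idx].tobytes().decode() for i, t in enumerate(aln.taxa)
    }
    return MultipleAlignment(rows, aln.moltype)


# ---------------------------------------------------------------------------
# back-translation and concatenation

_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = None


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate())


def back_translate(
    protein_aln: MultipleAlignment, cds: dict[str, SequenceRecord]
) -> MultipleAlignment:
    """Replace each aligned residue by its codon ('-' becomes '---').

    Each taxon's CDS must translate to its ungapped protein row; exactly one
    trailing stop codon is tolerated and dropped.
    """
    if protein_aln.moltype is not MolType.PROTEIN:
        raise ValueError("back_translate expects a protein alignment")
    rows: dict[str, str] = {}
    for taxon, row in protein_aln.rows.items():
        if taxon not in cds:
            raise FormatError(f"no CDS provided for taxon {taxon!r}")
        dna = cds[taxon].seq.replace("-", "")
        protein = row.replace("-", "")
        if len(dna) == 3 * len(protein) + 3 and dna[-3:] in _STOPS:
            dna = dna[:-3]
        if len(dna) != 3 * len(protein):
            raise FormatError(
                f"{taxon}: CDS length {len(dna)} does not match protein "
                f"length {len(protein)}"
            )
        translated = _translate(dna)
        for i, (a, b) in enumerate(zip(translated, protein)):
            if a != b:
                raise FormatError(
                    f"{taxon}: translation mismatch at residue {i} ({a!r} != {b!r})"
                )
        codons: list[str] = []
        pos = 0
        for ch in row:
            if ch == "-":
                codons.append("---")
            elif ch == "?":
                codons.append("???")
            else:
                codons.append(dna[3 * pos : 3 * pos + 3])
                pos += 1
        rows[taxon] = "".join(codons)
    return MultipleAlignment(rows, MolType.DNA)


def concat_supermatrix(
    alns: list[tuple[str, MultipleAlignment]], taxa: list[str]
) -> Supermatrix:
    """Concatenate gene alignments in input order over a master taxon list;
    taxa missing from a gene are filled with ``?``."""
    if not alns:
        raise ValueError("no alignments to concatenate")
    taxa_set = set(taxa)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for og_id, aln in alns:
        extra = set(aln.taxa) - taxa_set
        if extra:
            raise ValueError(f"{og_id}: taxa {sorted(extra)} not in the master list")
        for t in taxa:
            parts[t].append(aln.rows.get(t, "?" * aln.length))
        partitions.append((og_id, pos, pos + aln.length))
        pos += aln.length
    return Supermatrix(
        taxa=list(taxa),
        matrix={t: "".join(parts[t]) for t in taxa},
        partitions=partitions,
    )


def codon_position_mask(sm: Supermatrix, positions: set[int]) -> Supermatrix:
    """Sub-supermatrix of the selected codon positions (subset of {1,2,3})."""
    if not positions <= {1, 2, 3}:
        raise ValueError("positions must be a subset of {1, 2, 3}")
    offsets = sorted(p - 1 for p in positions)
    keep: list[int] = []
    partitions: list[tuple[str, int, int]] = []
    out_pos = 0
    for og, start, end in sm.partitions:
        if (end - start) % 3:
            raise ValueError(f"partition {og} length {end - start} not codon-sized")
        count = 0
        for codon_start in range(start, end, 3):
            for off in offsets:
                keep.append(codon_start + off)
                count += 1
        partitions.append((og, out_pos, out_pos + count))
        out_pos += count
    idx = np.array(keep, dtype=int)
    matrix = {}
    for t, row in sm.matrix.items():
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        matrix[t] = arr[idx].tobytes().decode()
    return Supermatrix(taxa=list(sm.taxa), matrix=matrix, partitions=partitions)


def write_partition_file(sm: Supermatrix, path: str | Path) -> None:
    """RAxML-style plain-text partition spans (1-based inclusive)."""
    with open(path, "w") as fh:
        for og, start, end in sm.partitions:
            fh.write(f"{og} = {start + 1}-{end}\n")
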