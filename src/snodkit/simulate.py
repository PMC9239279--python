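"""Synthetic genome communities with known evolutionary ground truth.

The generator emulates the statistical structure of a multi-species bacterial
community sampled around the species boundary: several groups whose members
are nearly identical (within-group nucleotide identity well above 95%) and
which are clearly separated from each other (between-group identity below
87%), a shared single-copy core genome, planted group-specific gene families,
occasional paralogs, fast-evolving gappy families, and a handful of
high-identity cross-group transfer events. Every planted feature is recorded
in a :class:`SyntheticTruth` so that downstream inferences (ortholog
clustering, core-gene filtering, tree support, species partitioning,
specific-gene detection, HGT screening) can be scored exactly.

Sequences evolve along a fixed genome tree under a uniform (Jukes-Cantor
style) nucleotide substitution process — the number of events on a branch is
Poisson(rate x branch length x sites), each event hits a uniform site and
replaces the base by one of the three alternatives uniformly — so the
expected identity after divergence d has the closed form
1/4 + 3/4 exp(-4d/3). Indels are codon multiples to preserve reading frame,
and substitutions that would create an in-frame stop are redrawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from Bio.Seq import Seq

from .io import GenomeMetadata, MolType, SequenceRecord, write_fasta

__all__ = [
    "CommunityConfig",
    "SyntheticTruth",
    "Community",
    "generate_community",
    "evolve_family",
    "jc_expected_identity",
]

_BASES = b"ACGT"
_STOPS = {b"TAA", b"TAG", b"TGA"}
_SENSE_CODONS = [
    bytes((a, b, c))
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if bytes((a, b, c)) not in _STOPS
]

_CODON_AA: dict[bytes, str] = {}


def _aa_of(codon: bytes) -> str:
    aa = _CODON_AA.get(codon)
    if aa is None:
        from Bio.Seq import Seq

        aa = str(Seq(codon.decode()).translate())
        _CODON_AA[codon] = aa
    return aa


def jc_expected_identity(d: float) -> float:
    """Expected nucleotide identity after divergence ``d`` subs/site."""
    return 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)


@dataclass(frozen=True)
class CommunityConfig:
    """Study conditions for a synthetic community.

    Defaults mirror the structure of the real 76-genome data set: seven
    ingroup species of sizes 3/45/4/1/3/2/17 plus one outgroup, a ~44-family
    single-copy core of which a tenth carries a planted paralog and a tenth
    evolves five times faster with elevated indels, two specific families per
    group planted at 80% annotation occupancy, and three cross-group
    transfers at >= 98% donor identity.
    """

    n_groups: int = 7
    genomes_per_group: tuple[int, ...] = (3, 45, 4, 1, 3, 2, 17)
    include_outgroup: bool = True
    n_core_families: int = 44
    n_specific_per_group: int = 2
    specific_occupancy: float = 0.8
    within_group_divergence: float = 0.02
    between_group_divergence: float = 0.18
    nonsyn_acceptance: float = 0.1
    outgroup_extra: float = 1.2
    indel_rate: float = 0.001
    paralog_fraction: float = 0.1
    hypervariable_fraction: float = 0.1
    hypervariable_rate_mult: float = 5.0
    n_hgt_events: int = 3
    hgt_divergence: float = 0.004
    n_clones: int = 2
    clone_divergence: float = 0.002
    gene_length_mean: int = 180
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genomes_per_group) != self.n_groups:
            raise ValueError(
                f"genomes_per_group has {len(self.genomes_per_group)} entries "
                f"for n_groups={self.n_groups}"
            )
        if not self.within_group_divergence < self.between_group_divergence:
            raise ValueError("within_group_divergence must be < between_group_divergence")
        for name in ("specific_occupancy", "paralog_fraction", "hypervariable_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if min(self.genomes_per_group) < 1 or self.n_core_families < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated community."""

    group_of: dict[str, str]
    core_families: list[str]
    paralog_families: list[str]
    hypervariable_families: list[str]
    specific_genes: dict[frozenset[str], list[str]]
    withheld: set[tuple[str, str]]
    hgt_events: list[tuple[str, str, str]]
    tree_newick: str

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group_of.values():
            if g != "outgroup" and g not in seen:
                seen.append(g)
        return seen

    def members(self, group: str) -> list[str]:
        return [g for g, grp in self.group_of.items() if grp == group]


@dataclass
class Community:
    """A generated community held in memory, writable to FASTA/TSV."""

    config: CommunityConfig
    genomes: list[str]
    genome_seqs: dict[str, str]
    proteomes: dict[str, list[SequenceRecord]]
    cds: dict[str, list[SequenceRecord]]
    metadata: list[GenomeMetadata]
    truth: SyntheticTruth

    def clustering_proteomes(self) -> dict[str, list[SequenceRecord]]:
        """Proteomes with withheld (annotation-missed) sequences removed.

        The withheld copies stay in :attr:`proteomes`, which therefore serves
        as the enrichment pool; this emulates genes missed by annotation that
        a sensitive orthology search can still recover.
        """
        withheld = self.truth.withheld
        return {
            g: [r for r in recs if (g, r.id) not in withheld]
            for g, recs in self.proteomes.items()
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        for sub in ("genomes", "proteomes", "cds", "truth"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        for g in self.genomes:
            write_fasta(
                [SequenceRecord(g, self.genome_seqs[g], MolType.DNA)],
                out / "genomes" / f"{g}.fna",
            )
            write_fasta(self.proteomes[g], out / "proteomes" / f"{g}.faa")
            write_fasta(self.cds[g], out / "cds" / f"{g}.ffn")
        with open(out / "truth" / "groups.tsv", "w") as fh:
            fh.write("genome\tgroup\n")
            for g in self.genomes:
                fh.write(f"{g}\t{self.truth.group_of[g]}\n")
        with open(out / "truth" / "specific_genes.tsv", "w") as fh:
            fh.write("group_set\tfamily\n")
            for gs in sorted(self.truth.specific_genes, key=sorted):
                for fam in self.truth.specific_genes[gs]:
                    fh.write(f"{'+'.join(sorted(gs))}\t{fam}\n")
        with open(out / "truth" / "hgt_events.tsv", "w") as fh:
            fh.write("donor\trecipient\tfamily\n")
            for d, r, fam in self.truth.hgt_events:
                fh.write(f"{d}\t{r}\t{fam}\n")
        with open(out / "truth" / "tree.nwk", "w") as fh:
            fh.write(self.truth.tree_newick + "\n")
        with open(out / "metadata.tsv", "w") as fh:
            fh.write(
                "accession\tstrain\tspecies\tgroup\thost\torigin\tcompleteness\t"
                "contamination\tlength\tn_contigs\tn50\tderep_representative\n"
            )
            for m in self.metadata:
                fh.write(
                    f"{m.accession}\t{m.strain}\t{m.species}\t{m.group}\t{m.host}\t"
                    f"{m.origin}\t{m.completeness}\t{m.contamination}\t{m.length}\t"
                    f"{m.n_contigs}\t{m.n50}\tno\n"
                )


# ---------------------------------------------------------------------------
# sequence evolution


def _random_cds(rng: np.random.Generator, n_codons: int) -> bytearray:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    out = bytearray()
    for i in idx:
        out += _SENSE_CODONS[i]
    return out


def _random_dna(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(bytes(_BASES[i] for i in rng.integers(0, 4, size=n)))


def _creates_stop(seq: bytearray, pos: int) -> bool:
    start = (pos // 3) * 3
    return bytes(seq[start : start + 3]) in _STOPS


def _mutate(
    seq: bytearray,
    rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    coding: bool,
    nonsyn_accept: float = 1.0,
) -> bytearray:
    """One branch of evolution: Poisson substitutions, then Poisson indels.

    ``nonsyn_accept`` < 1 models purifying selection: a proposed substitution
    that changes the encoded amino acid is accepted with that probability and
    otherwise redrawn, so the realized substitution count stays Poisson while
    events concentrate on synonymous sites.
    """
    seq = bytearray(seq)
    n = len(seq)
    n_sub = rng.poisson(rate * n)
    for _ in range(n_sub):
        for _attempt in range(30):
            pos = int(rng.integers(0, n))
            old = seq[pos]
            offset = int(rng.integers(1, 4))
            new = _BASES[(_BASES.index(old) + offset) % 4]
            if coding:
                start = (pos // 3) * 3
                old_codon = bytes(seq[start : start + 3])
            seq[pos] = new
            if coding:
                new_codon = bytes(seq[start : start + 3])
                if new_codon in _STOPS:
                    seq[pos] = old
                    continue
                if (
                    nonsyn_accept < 1.0
                    and _aa_of(new_codon) != _aa_of(old_codon)
                    and rng.random() >= nonsyn_accept
                ):
                    seq[pos] = old
                    continue
            break
    n_indel = rng.poisson(indel_rate * n)
    for _ in range(n_indel):
        if coding:
            n_codons = len(seq) // 3
            k = int(rng.integers(1, 3))  # 1-2 codons
            if rng.random() < 0.5 and n_codons > k + 10:
                c = int(rng.integers(0, n_codons - k))
                del seq[3 * c : 3 * (c + k)]
            else:
                c = int(rng.integers(0, n_codons + 1))
                ins = bytearray()
                for i in rng.integers(0, len(_SENSE_CODONS), size=k):
                    ins += _SENSE_CODONS[i]
                seq[3 * c : 3 * c] = ins
        else:
            k = int(rng.integers(1, 7))
            if rng.random() < 0.5 and len(seq) > k + 20:
                p = int(rng.integers(0, len(seq) - k))
                del seq[p : p + k]
            else:
                p = int(rng.integers(0, len(seq) + 1))
                seq[p:p] = _random_dna(rng, k)
    return seq


def _evolve_on_tree(
    ancestor: bytearray,
    tree: dendropy.Tree,
    rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    coding: bool,
    nonsyn_accept: float = 1.0,
) -> dict[str, bytearray]:
    """Evolve ``ancestor`` from the root of ``tree`` to every leaf."""
    leaves: dict[str, bytearray] = {}
    stack = [(tree.seed_node, ancestor)]
    while stack:
        node, seq = stack.pop()
        bl = node.edge.length or 0.0
        if bl > 0:
            seq = _mutate(seq, rate * bl, indel_rate * bl, rng, coding, nonsyn_accept)
        children = node.child_nodes()
        if not children:
            leaves[node.taxon.label] = seq
        else:
            # deterministic order: dendropy preserves input child order
            for child in reversed(children):
                stack.append((child, bytearray(seq)))
    return leaves


def _check_coding(seq: str) -> None:
    if len(seq) % 3:
        raise ValueError("coding sequence length not divisible by 3")
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in ("TAA", "TAG", "TGA"):
            raise ValueError(f"in-frame stop codon at position {i}")


def evolve_family(
    ancestor: SequenceRecord,
    tree: str,
    rate: float = 1.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    nonsyn_acceptance: float = 1.0,
) -> dict[str, SequenceRecord]:
    """Evolve a coding ancestor along a Newick tree with branch lengths.

    Branch lengths are in substitutions/site and are scaled by ``rate``;
    indel events (codon multiples) occur at ``indel_rate`` x branch length
    per site. Returns one record per leaf, keyed by leaf label.
    """
    _check_coding(ancestor.seq)
    dtree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    rng = np.random.default_rng(seed)
    leaves = _evolve_on_tree(
        bytearray(ancestor.seq.encode()), dtree, rate, indel_rate, rng,
        coding=True, nonsyn_accept=nonsyn_acceptance,
    )
    return {
        label: SequenceRecord(f"{label}|{ancestor.id}", bytes(seq).decode(), MolType.DNA)
        for label, seq in leaves.items()
    }


# ---------------------------------------------------------------------------
# community assembly


def _community_tree(config: CommunityConfig) -> tuple[str, dict[str, list[str]]]:
    """Genome tree newick and group membership map.

    The first group diverges earliest within the ingroup; the remaining
    groups form a balanced subtree. Sister groups sit exactly
    ``between_group_divergence`` apart leaf-to-leaf; deeper pairs are
    slightly more divergent via short internal edges.
    """
    w = config.within_group_divergence
    b = config.between_group_divergence
    eps = b * 0.25
    pendant = (b - w) / 2.0
    groups = [f"group{i + 1}" for i in range(config.n_groups)]
    members = {
        g: [f"{g}_{j + 1:02d}" for j in range(n)]
        for g, n in zip(groups, config.genomes_per_group)
    }

    def grp(g: str) -> str:
        tips = members[g]
        if len(tips) == 1:
            return f"{tips[0]}:{pendant + w / 2}"
        inner = ",".join(f"{t}:{w / 2}" for t in tips)
        return f"({inner}):{pendant}"

    def bal(gs: list[str]) -> str:
        if len(gs) == 1:
            return grp(gs[0])
        mid = len(gs) // 2
        return f"({bal(gs[:mid])},{bal(gs[mid:])}):{eps}"

    if config.n_groups == 1:
        ingroup = grp(groups[0])
    else:
        ingroup = f"({grp(groups[0])},{bal(groups[1:])}):{eps}"
    if config.include_outgroup:
        members["outgroup"] = ["outgroup_01"]
        out_bl = b * config.outgroup_extra
        newick = f"(outgroup_01:{out_bl},{ingroup});"
    else:
        newick = ingroup.rsplit(":", 1)[0] + ";"
    return newick, members


def _subtree_newick(tree: dendropy.Tree, leaves: list[str]) -> dendropy.Tree:
    return tree.extract_tree_with_taxa_labels(labels=set(leaves))


def generate_community(
    config: CommunityConfig, out_dir: str | Path | None = None
) -> Community:
    """Generate a full community; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    newick, members = _community_tree(config)
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    group_names = [f"group{i + 1}" for i in range(config.n_groups)]
    group_of: dict[str, str] = {}
    for g, tips in members.items():
        for t in tips:
            group_of[t] = g
    genomes = [t for g in group_names for t in members[g]]
    if config.include_outgroup:
        genomes += members["outgroup"]
    ingroup = [g for g in genomes if group_of[g] != "outgroup"]

    # -- family bookkeeping
    n_hyper = math.ceil(config.hypervariable_fraction * config.n_core_families)
    n_para = math.ceil(config.paralog_fraction * config.n_core_families)
    fams: list[tuple[str, str]] = []  # (family id, kind)
    for i in range(config.n_core_families):
        if i < n_hyper:
            fams.append((f"hvar{i + 1:03d}", "hyper"))
        elif i < n_hyper + n_para:
            fams.append((f"para{i + 1:03d}", "paralog"))
        else:
            fams.append((f"core{i + 1:03d}", "core"))

    def gene_len() -> int:
        mean = config.gene_length_mean
        return max(60, int(rng.normal(mean, mean / 5)))

    # evolve shared families over the full tree
    family_cds: dict[str, dict[str, bytearray]] = {}
    family_members: dict[str, list[str]] = {}
    family_spacers: dict[str, dict[str, bytearray]] = {}
    for fam, kind in fams:
        mult = config.hypervariable_rate_mult if kind == "hyper" else 1.0
        indel_mult = 3.0 if kind == "hyper" else 1.0
        anc = _random_cds(rng, gene_len())
        family_cds[fam] = _evolve_on_tree(
            anc, tree, mult, config.indel_rate * indel_mult * mult, rng,
            coding=True, nonsyn_accept=config.nonsyn_acceptance,
        )
        family_members[fam] = list(genomes)
        spc = _random_dna(rng, int(rng.integers(50, 201)))
        family_spacers[fam] = _evolve_on_tree(spc, tree, 1.0, 0.0, rng, coding=False)

    # specific families: single groups, one pair, one all-groups set
    specific_sets: list[frozenset[str]] = []
    if config.n_specific_per_group:
        specific_sets = [frozenset([g]) for g in group_names]
        if config.n_groups >= 2:
            specific_sets.append(frozenset(group_names[:2]))
        if config.n_groups >= 3:
            specific_sets.append(frozenset(group_names))
    specific_genes: dict[frozenset[str], list[str]] = {}
    withheld: set[tuple[str, str]] = set()
    for gs in specific_sets:
        if len(gs) == 1:
            n_fam = config.n_specific_per_group
            tag = f"spec_{next(iter(gs))}"
        elif len(gs) == config.n_groups:
            n_fam, tag = 1, "spec_all"
        else:
            n_fam, tag = 1, "spec_" + "_".join(sorted(gs))
        gs_members = [g for g in ingroup if group_of[g] in gs]
        sub = _subtree_newick(tree, gs_members) if len(gs_members) > 1 else None
        specific_genes[gs] = []
        for j in range(n_fam):
            fam = f"{tag}_{j + 1}" if n_fam > 1 else tag
            anc = _random_cds(rng, gene_len())
            if sub is None:
                leaf = {gs_members[0]: _mutate(anc, config.within_group_divergence / 2,
                                              config.indel_rate, rng, True,
                                              config.nonsyn_acceptance)}
            else:
                leaf = _evolve_on_tree(anc, sub, 1.0, config.indel_rate, rng,
                                       coding=True, nonsyn_accept=config.nonsyn_acceptance)
            family_cds[fam] = leaf
            family_members[fam] = gs_members
            spc = _random_dna(rng, int(rng.integers(50, 201)))
            if sub is None:
                family_spacers[fam] = {gs_members[0]: spc}
            else:
                family_spacers[fam] = _evolve_on_tree(spc, sub, 1.0, 0.0, rng, coding=False)
            specific_genes[gs].append(fam)
            # annotation misses: present in the proteome pool, absent from
            # the clustering input, up to the configured occupancy
            n_miss = int(math.floor((1 - config.specific_occupancy) * len(gs_members)))
            if n_miss:
                missed = rng.choice(len(gs_members), size=n_miss, replace=False)
                for mi in missed:
                    withheld.add((gs_members[mi], f"{gs_members[mi]}|{fam}"))

    # clones: near-identical copies of members of the largest group
    clone_sources: list[str] = []
    if config.n_clones:
        big = max(group_names, key=lambda g: len(members[g]))
        pool = members[big]
        for i in range(config.n_clones):
            src = pool[i % len(pool)]
            clone = f"{big}_c{i + 1}"
            group_of[clone] = big
            genomes.append(clone)
            ingroup.append(clone)
            clone_sources.append(src)
            for fam in family_cds:
                if src in family_cds[fam]:
                    family_cds[fam][clone] = _mutate(
                        family_cds[fam][src], config.clone_divergence, 0.0, rng, True
                    )
                    family_members[fam] = family_members.get(fam, []) + [clone]
                    family_spacers[fam][clone] = _mutate(
                        family_spacers[fam][src], config.clone_divergence, 0.0, rng, False
                    )

    # horizontal transfers: replace a recipient's copy of a clean core family
    # with a barely diverged donor copy
    clean_core = [f for f, k in fams if k == "core"]
    hgt_events: list[tuple[str, str, str]] = []
    if config.n_hgt_events and config.n_groups >= 2 and clean_core:
        fam_choice = rng.choice(len(clean_core), size=min(config.n_hgt_events, len(clean_core)), replace=False)
        for fi in fam_choice:
            fam = clean_core[fi]
            gi, gj = rng.choice(config.n_groups, size=2, replace=False)
            donor_group, recip_group = group_names[gi], group_names[gj]
            donor = members[donor_group][int(rng.integers(0, len(members[donor_group])))]
            recip = members[recip_group][int(rng.integers(0, len(members[recip_group])))]
            donor_seq = family_cds[fam][donor]
            donor_aa = str(Seq(bytes(donor_seq).decode()).translate())
            # the planted copy must stay >= 98% identical to the donor at
            # the protein level; redraw if Poisson noise overshoots
            for _try in range(20):
                copy = _mutate(donor_seq, config.hgt_divergence, 0.0, rng,
                               coding=True, nonsyn_accept=config.nonsyn_acceptance)
                copy_aa = str(Seq(bytes(copy).decode()).translate())
                same = sum(a == b for a, b in zip(donor_aa, copy_aa))
                if same / len(donor_aa) >= 0.985:
                    break
            family_cds[fam][recip] = copy
            hgt_events.append((donor, recip, fam))

    # paralogs: duplicate one random ingroup genome's copy
    paralog_fams = [f for f, k in fams if k == "paralog"]
    paralog_copy: dict[str, tuple[str, bytearray]] = {}
    for fam in paralog_fams:
        host = ingroup[int(rng.integers(0, len(ingroup)))]
        paralog_copy[fam] = (host, _mutate(family_cds[fam][host], 0.01, 0.0, rng, True))

    # -- assemble genomes
    fam_order = [f for f, _ in fams] + [
        fam for gs in specific_sets for fam in specific_genes[gs]
    ]
    genome_seqs: dict[str, str] = {}
    proteomes: dict[str, list[SequenceRecord]] = {}
    cds_records: dict[str, list[SequenceRecord]] = {}
    for g in genomes:
        parts: list[bytes] = []
        prots: list[SequenceRecord] = []
        cdss: list[SequenceRecord] = []
        for fam in fam_order:
            if g not in family_cds[fam]:
                continue
            seq = bytes(family_cds[fam][g])
            parts.append(bytes(family_spacers[fam].get(g, b"")) )
            parts.append(seq)
            sid = f"{g}|{fam}"
            cdss.append(SequenceRecord(sid, seq.decode(), MolType.DNA))
            prots.append(
                SequenceRecord(sid, str(Seq(seq.decode()).translate()), MolType.PROTEIN)
            )
            if fam in paralog_copy and paralog_copy[fam][0] == g:
                dup = bytes(paralog_copy[fam][1])
                parts.append(bytes(_random_dna(rng, int(rng.integers(50, 201)))))
                parts.append(dup)
                sid2 = f"{g}|{fam}|copy2"
                cdss.append(SequenceRecord(sid2, dup.decode(), MolType.DNA))
                prots.append(
                    SequenceRecord(sid2, str(Seq(dup.decode()).translate()), MolType.PROTEIN)
                )
        parts.append(bytes(_random_dna(rng, int(rng.integers(50, 201)))))
        genome_seqs[g] = b"".join(parts).decode()
        proteomes[g] = prots
        cds_records[g] = cdss

    metadata = [
        GenomeMetadata(
            accession=g,
            strain=g,
            group=group_of[g],
            host="synthetic",
            completeness=round(float(rng.uniform(96, 100)), 2),
            contamination=round(float(rng.uniform(0, 2)), 2),
            length=len(genome_seqs[g]),
            n_contigs=int(rng.integers(10, 200)),
            n50=max(1, len(genome_seqs[g]) // int(rng.integers(2, 40))),
            species="synthetic",
        )
        for g in genomes
    ]

    truth = SyntheticTruth(
        group_of=group_of,
        core_families=clean_core,
        paralog_families=paralog_fams,
        hypervariable_families=[f for f, k in fams if k == "hyper"],
        specific_genes=specific_genes,
        withheld=withheld,
        hgt_events=hgt_events,
        tree_newick=newick,
    )
    community = Community(
        config=config,
        genomes=genomes,
        genome_seqs=genome_seqs,
        proteomes=proteomes,
        cds=cds_records,
        metadata=metadata,
        truth=truth,
    )
    if out_dir is not None:
        community.write(out_dir)
    return community
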