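"""Synthetic genomes with a known triplication / tandem-duplication history.

The generator emulates the evolutionary scenario the analysis modules are
built for: a reference-like ancestor genome; a whole-genome triplication
(WGT) in a descendant lineage producing three subgenomes (LF, MF1, MF2)
that then lose genes independently (fractionation, gene-wise Bernoulli
retention); tandem duplication both *before* the split (arrays present in
the ancestor and therefore carried into syntenic positions of every
subgenome) and *after* it (lineage-specific copies next to their parent);
codon pairs evolved at a known dN/dS ratio omega; and cluster-structured
tissue expression. Every planted event is recorded in a
:class:`DuplicationTruth` so downstream inference can be scored exactly.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy.random.Generator`` streams; identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kaks import BASES, STOP_CODONS, CodonAlignmentPair, translate_codon

SUBGENOMES = ("LF", "MF1", "MF2")
DEFAULT_TISSUES = ("root", "stem", "leaf", "flower", "silique", "callus")

#: gene spacing used when laying coordinates (bp); genes are 2 kb long
_GENE_PITCH = 3000
_GENE_LEN = 2000


class ConfigurationError(ValueError):
    """Infeasible or invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted evolutionary scenario.

    ``retention_probs`` defaults mirror the least/medium/most fractionated
    subgenome ordering (LF keeps the most genes). ``n_families`` may be
    left None, in which case it is derived from ``family_size_mean``.
    """

    seed: int = 0
    n_chromosomes: int = 5
    genes_per_chromosome: int = 200
    n_families: int | None = None
    family_size_mean: float = 50.0
    retention_probs: dict = field(
        default_factory=lambda: {"LF": 0.70, "MF1": 0.45, "MF2": 0.30}
    )
    tandem_rate_pre_split: float = 0.05
    tandem_rate_post_split: float = 0.02
    max_array_size: int = 4
    codon_length: int = 300
    omega_values: tuple = (0.2,)
    ks_target: float = 0.3
    n_tissues: int = 6
    n_expression_clusters: int = 5
    noise_sd: float = 0.3
    #: minimum pairwise Spearman distance between cluster mean profiles;
    #: guarantees clusters are separable by rank-based distances
    profile_separation: float = 0.5
    #: same-family genes in the ancestor are kept at least this many ranks
    #: apart (outside planted arrays) so planted arrays never merge
    family_spacing: int = 4

    def total_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome

    def resolved_n_families(self) -> int:
        if self.n_families is not None:
            return self.n_families
        return max(1, round(self.total_genes() / self.family_size_mean))

    def validate(self) -> None:
        probs = list(self.retention_probs.values()) + [
            self.tandem_rate_pre_split,
            self.tandem_rate_post_split,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if set(self.retention_probs) != set(SUBGENOMES):
            raise ConfigurationError(f"retention_probs must cover {SUBGENOMES}")
        if self.codon_length < 30:
            raise ConfigurationError("codon_length must be >= 30")
        if self.max_array_size < 2:
            raise ConfigurationError("max_array_size must be >= 2")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ConfigurationError("need at least one chromosome and one gene")
        nf = self.resolved_n_families()
        if nf > self.total_genes():
            raise ConfigurationError("more families than gene slots")
        if nf <= self.family_spacing:
            raise ConfigurationError(
                "need more families than family_spacing to lay out the ancestor"
            )
        if self.n_expression_clusters < 1:
            raise ConfigurationError("n_expression_clusters must be >= 1")
        if not self.omega_values or any(w < 0 for w in self.omega_values):
            raise ConfigurationError("omega_values must be nonnegative and nonempty")
        if self.ks_target < 0:
            raise ConfigurationError("ks_target must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Named generator: one integer stream index per operation."""
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


@dataclass
class Genome:
    """One genome: gene table (with ranks) and family assignments."""

    species: str
    genes: pd.DataFrame
    families: pd.DataFrame


@dataclass
class AncestorGenome(Genome):
    #: planted pre-split tandem arrays, as ordered tuples of gene ids
    pre_split_arrays: list = field(default_factory=list)


@dataclass
class DuplicationTruth:
    """The simulator's planted history, used to score recovered inferences."""

    #: long table: species, subgenome, ref_gene, descendant_gene
    ortholog_map: pd.DataFrame
    #: descendant gene id -> "wgt" (retained triplication copy) or
    #: "td_copy" (post-split tandem duplicate)
    origin: dict
    #: descendant gene id -> ancestral source gene id
    source_ref: dict
    #: WGT-retained members of planted pre-split arrays that still have an
    #: adjacent array partner in their subgenome (detectable ancient genes)
    ancient_tandem_genes: set
    #: post-split tandem copies (lineage-specific by construction)
    lineage_specific_tandem_genes: set
    #: per (species, subgenome): planted arrays fully lost or reduced to a
    #: single member by fractionation (age is undecidable for these)
    array_attrition: pd.DataFrame
    pre_split_arrays: list = field(default_factory=list)


def _layout_coordinates(order: pd.DataFrame) -> pd.DataFrame:
    """Assign 1-based coordinates and ranks from the final gene order."""
    out = order.copy()
    out["rank"] = out.groupby("chromosome").cumcount()
    out["start"] = 1 + out["rank"] * _GENE_PITCH
    out["end"] = out["start"] + _GENE_LEN - 1
    return out


def _array_size(rng: np.random.Generator, max_size: int) -> int:
    """Array size in 2..max_size, geometric-decay preference for small arrays."""
    size = 2
    while size < max_size and rng.random() < 0.5:
        size += 1
    return size


def simulate_ancestor(config: SimulationConfig) -> AncestorGenome:
    """Build the reference-like ancestor genome.

    Genes are laid gap-free on ``n_chromosomes`` chromosomes; families are
    drawn with gamma-distributed weights under the constraint that two
    same-family genes are never closer than ``family_spacing`` ranks —
    except inside planted tandem arrays, planted per seed gene at
    ``tandem_rate_pre_split`` as adjacent same-family copies.
    """
    config.validate()
    rng = _rng(config, 0)
    nf = config.resolved_n_families()
    fam_names = [f"FAM{i:03d}" for i in range(nf)]
    weights = rng.gamma(shape=2.0, scale=1.0, size=nf)
    weights /= weights.sum()

    rows = []  # (gene_id, chromosome, family, strand)
    arrays: list[tuple[str, ...]] = []
    gene_no = 0

    def new_gene(chrom: str, family: str, strand: str) -> str:
        nonlocal gene_no
        gene_no += 1
        gid = f"REF{gene_no:06d}"
        rows.append((gid, chrom, family, strand))
        return gid

    for c in range(config.n_chromosomes):
        chrom = f"refChr{c + 1:02d}"
        recent: list[str] = []  # families of the last family_spacing genes
        for _ in range(config.genes_per_chromosome):
            allowed = [i for i, f in enumerate(fam_names) if f not in recent]
            w = weights[allowed]
            fam = fam_names[allowed[int(rng.choice(len(allowed), p=w / w.sum()))]]
            strand = "+" if rng.random() < 0.5 else "-"
            seed_gene = new_gene(chrom, fam, strand)
            if rng.random() < config.tandem_rate_pre_split:
                size = _array_size(rng, config.max_array_size)
                members = [seed_gene]
                for _ in range(size - 1):
                    members.append(new_gene(chrom, fam, strand))
                arrays.append(tuple(members))
                # copies count toward the spacing window like any other gene
                recent = (recent + [fam] * size)[-config.family_spacing:]
            else:
                recent = (recent + [fam])[-config.family_spacing:]

    order = pd.DataFrame(rows, columns=["gene_id", "chromosome", "family", "strand"])
    genes = _layout_coordinates(order)[
        ["gene_id", "chromosome", "start", "end", "strand", "rank"]
    ]
    families = order[["gene_id", "family"]].copy()
    families["species"] = "ancestor"
    return AncestorGenome("ancestor", genes, families, pre_split_arrays=arrays)


def simulate_triplication_descendants(
    ancestor: AncestorGenome,
    config: SimulationConfig,
    n_descendants: int = 2,
) -> tuple[list[Genome], pd.DataFrame, pd.DataFrame, DuplicationTruth]:
    """Triplicate the ancestor into descendants and fractionate.

    Each ancestor gene is copied into the three subgenomes of each
    descendant and independently retained with
    ``retention_probs[subgenome]``; post-split tandem duplicates are then
    added per retained gene at ``tandem_rate_post_split``. Returns
    ``(descendants, subgenome_map, anchors, truth)`` where ``anchors`` is
    the reference-to-descendant homology table (one anchor per descendant
    gene to its true ancestral source, tandem copies scoring lower than
    triplication copies, plus ~1% decoy pairs above the e-value cutoff).
    """
    config.validate()
    rng = _rng(config, 1)
    anc_genes = ancestor.genes
    fam_of = dict(zip(ancestor.families["gene_id"], ancestor.families["family"]))
    array_of = {}
    for arr in ancestor.pre_split_arrays:
        for g in arr:
            array_of[g] = arr

    descendants: list[Genome] = []
    map_rows, sg_rows, anchor_rows, attrition_rows = [], [], [], []
    origin: dict[str, str] = {}
    source_ref: dict[str, str] = {}
    ancient: set[str] = set()
    lineage: set[str] = set()

    for d in range(1, n_descendants + 1):
        species = f"desc{d}"
        counter = 0
        drows = []  # gene_id, chromosome, family, strand, source, origin

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"D{d}G{counter:06d}"

        for sg in SUBGENOMES:
            p_keep = config.retention_probs[sg]
            for chrom, sub in anc_genes.groupby("chromosome", sort=True):
                new_chrom = f"d{d}_{sg}_{chrom}"
                sub = sub.sort_values("rank")
                keep = rng.random(len(sub)) < p_keep
                retained_by_array: dict[tuple, list[str]] = {}
                for (row, kept) in zip(sub.itertuples(index=False), keep):
                    if not kept:
                        continue
                    gid = new_id()
                    drows.append(
                        (gid, new_chrom, fam_of[row.gene_id], row.strand,
                         row.gene_id, "wgt")
                    )
                    origin[gid] = "wgt"
                    source_ref[gid] = row.gene_id
                    map_rows.append((species, sg, row.gene_id, gid))
                    arr = array_of.get(row.gene_id)
                    if arr is not None:
                        retained_by_array.setdefault(arr, []).append(gid)
                    if rng.random() < config.tandem_rate_post_split:
                        n_copies = _array_size(rng, config.max_array_size) - 1
                        for _ in range(n_copies):
                            cid = new_id()
                            drows.append(
                                (cid, new_chrom, fam_of[row.gene_id], row.strand,
                                 row.gene_id, "td_copy")
                            )
                            origin[cid] = "td_copy"
                            source_ref[cid] = row.gene_id
                            lineage.add(cid)
                # planted-array bookkeeping for this subgenome copy
                for arr in {array_of[g] for g in sub["gene_id"] if g in array_of}:
                    kept_members = retained_by_array.get(arr, [])
                    if len(kept_members) >= 2:
                        ancient.update(kept_members)
                    else:
                        attrition_rows.append(
                            (species, sg, ",".join(arr), len(kept_members))
                        )
                n_on_chrom = sum(1 for r in drows if r[1] == new_chrom)
                sg_rows.append(
                    (new_chrom, 1, max(n_on_chrom, 1) * _GENE_PITCH + _GENE_LEN, sg)
                )

        dgenes = pd.DataFrame(
            drows,
            columns=["gene_id", "chromosome", "family", "strand", "source", "origin"],
        )
        laid = _layout_coordinates(dgenes)
        genes = laid[["gene_id", "chromosome", "start", "end", "strand", "rank"]]
        families = laid[["gene_id", "family"]].copy()
        families["species"] = species
        descendants.append(Genome(species, genes, families))

        for row in laid.itertuples(index=False):
            score = (
                rng.uniform(80.0, 100.0)
                if row.origin == "wgt"
                else rng.uniform(50.0, 70.0)
            )
            anchor_rows.append(
                (row.source, row.gene_id, round(score, 2),
                 10.0 ** -rng.uniform(30.0, 180.0))
            )

    anchors = pd.DataFrame(
        anchor_rows, columns=["ref_gene", "target_gene", "score", "significance"]
    )
    if len(anchors):
        n_decoys = max(1, len(anchors) // 100)
        decoy_ref = anc_genes["gene_id"].to_numpy()[
            rng.integers(0, len(anc_genes), n_decoys)
        ]
        all_targets = anchors["target_gene"].to_numpy()
        decoy_tgt = all_targets[rng.integers(0, len(all_targets), n_decoys)]
        decoys = pd.DataFrame(
            {
                "ref_gene": decoy_ref,
                "target_gene": decoy_tgt,
                "score": np.round(rng.uniform(40.0, 60.0, n_decoys), 2),
                "significance": 10.0 ** -rng.uniform(5.0, 19.0, n_decoys),
            }
        )
        anchors = pd.concat([anchors, decoys], ignore_index=True)

    subgenome_map = pd.DataFrame(
        sg_rows, columns=["chromosome", "start", "end", "subgenome"]
    ).drop_duplicates(subset="chromosome", keep="last").reset_index(drop=True)

    truth = DuplicationTruth(
        ortholog_map=pd.DataFrame(
            map_rows, columns=["species", "subgenome", "ref_gene", "descendant_gene"]
        ),
        origin=origin,
        source_ref=source_ref,
        ancient_tandem_genes=ancient,
        lineage_specific_tandem_genes=lineage,
        array_attrition=pd.DataFrame(
            attrition_rows,
            columns=["species", "subgenome", "array", "members_retained"],
        ),
        pre_split_arrays=list(ancestor.pre_split_arrays),
    )
    return descendants, subgenome_map, anchors, truth


_SENSE_CODONS = sorted(
    c for c in ("".join((a, b, g)) for a in BASES for b in BASES for g in BASES)
    if c not in STOP_CODONS
)

#: expected synonymous proportion saturates (JC undefined) near ks 2-3;
#: configs beyond this are flagged rather than rejected
SATURATION_KS = 2.0


def evolve_codon_pairs(
    n_pairs: int, config: SimulationConfig
) -> tuple[list[CodonAlignmentPair], pd.DataFrame]:
    """Evolve codon-aligned pairs at planted omega values.

    Each pair starts from a random stop-free codon sequence; one copy
    accumulates a Poisson(3 * L * ks_target) number of proposed point
    mutations, accepting synonymous changes always, nonsynonymous changes
    with probability omega, and stop-creating changes never. This makes
    the expected NG86 Ks approach ``ks_target`` and the expected Ka/Ks
    approach omega. Pairs cycle through ``omega_values``.

    Returns the pairs plus a truth table (pair_id, omega, saturation
    warning flag).
    """
    config.validate()
    rng = _rng(config, 2)
    L = config.codon_length
    warn = config.ks_target >= SATURATION_KS
    pairs, rows = [], []
    for i in range(n_pairs):
        omega = float(config.omega_values[i % len(config.omega_values)])
        codons = [_SENSE_CODONS[j] for j in rng.integers(0, len(_SENSE_CODONS), L)]
        seq_a = "".join(codons)
        evolved = list(codons)
        n_events = rng.poisson(3.0 * L * config.ks_target)
        for _ in range(n_events):
            site = int(rng.integers(0, 3 * L))
            ci, pos = divmod(site, 3)
            cur = evolved[ci]
            alt = [b for b in BASES if b != cur[pos]][int(rng.integers(0, 3))]
            mutant = cur[:pos] + alt + cur[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if translate_codon(mutant) != translate_codon(cur):
                if rng.random() >= omega:
                    continue
            evolved[ci] = mutant
        pair_id = f"pair{i + 1:04d}"
        pairs.append(CodonAlignmentPair(pair_id, seq_a, "".join(evolved)))
        rows.append((pair_id, omega, warn))
    table = pd.DataFrame(rows, columns=["pair_id", "omega", "saturation_warning"])
    return pairs, table


def simulate_expression(
    gene_ids, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Cluster-structured tissue expression with lognormal noise.

    Each cluster gets a distinct tissue mean profile (distinct rank order
    across tissues, so rank-based distances separate clusters); a gene's
    row is its cluster profile times entry-wise exp(N(0, noise_sd)).
    Returns (matrix, labels).
    """
    config.validate()
    gene_ids = list(gene_ids)
    k = config.n_expression_clusters
    if k > len(gene_ids):
        raise ConfigurationError("n_expression_clusters exceeds number of genes")
    rng = _rng(config, 3)
    nt = config.n_tissues
    tissues = list(DEFAULT_TISSUES[:nt]) + [
        f"tissue{i + 1}" for i in range(len(DEFAULT_TISSUES), nt)
    ]

    from scipy.stats import rankdata

    def _rank_distance(a, b):
        ra, rb = rankdata(a), rankdata(b)
        ra, rb = ra - ra.mean(), rb - rb.mean()
        return 1.0 - float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))

    profiles: list[np.ndarray] = []
    for _ in range(k):
        for _attempt in range(5000):
            prof = rng.lognormal(mean=3.0, sigma=1.0, size=nt)
            if all(
                _rank_distance(prof, p) >= config.profile_separation
                for p in profiles
            ):
                break
        else:
            raise ConfigurationError(
                "could not draw sufficiently distinct cluster profiles; "
                "lower n_expression_clusters or profile_separation"
            )
        profiles.append(prof)
    profiles = np.array(profiles)

    perm = rng.permutation(len(gene_ids))
    labels = np.empty(len(gene_ids), dtype=int)
    labels[perm] = np.arange(len(gene_ids)) % k

    noise = np.exp(rng.normal(0.0, config.noise_sd, size=(len(gene_ids), nt)))
    values = profiles[labels] * noise
    matrix = pd.DataFrame(values, index=gene_ids, columns=tissues)
    return matrix, pd.Series(labels, index=gene_ids, name="cluster")


def export_scenario(outdir, ancestor, descendants, subgenome_map, anchors, truth,
                    config: SimulationConfig) -> None:
    """Write a simulated scenario as GFF3 + TSV + YAML config echo."""
    import yaml

    from .catalog import write_gff3
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_gff3(ancestor.genes, out / "ancestor.gff3")
    ancestor.families.to_csv(out / "ancestor_families.tsv", sep="\t", index=False)
    for g in descendants:
        write_gff3(g.genes, out / f"{g.species}.gff3")
        g.families.to_csv(out / f"{g.species}_families.tsv", sep="\t", index=False)
    subgenome_map.to_csv(out / "subgenome_map.tsv", sep="\t", index=False)
    anchors.to_csv(out / "anchors.tsv", sep="\t", index=False)
    truth.ortholog_map.to_csv(out / "truth_ortholog_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": sorted(truth.origin),
            "origin": [truth.origin[g] for g in sorted(truth.origin)],
            "source_ref": [truth.source_ref[g] for g in sorted(truth.origin)],
        }
    ).to_csv(out / "truth_origin.tsv", sep="\t", index=False)
    truth.array_attrition.to_csv(out / "truth_array_attrition.tsv", sep="\t", index=False)
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in config.__dict__.items()}
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def write_pairs_fasta(pairs, path, tag_a: str = "ref", tag_b: str = "desc") -> None:
    """Write codon-aligned pairs as FASTA, two records per pair."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.pair_id}|{tag_a}\n{p.seq_a}\n")
            fh.write(f">{p.pair_id}|{tag_b}\n{p.seq_b}\n")


def read_pairs_fasta(path) -> list[CodonAlignmentPair]:
    """Read codon-aligned pairs written by :func:`write_pairs_fasta`."""
    from Bio import SeqIO

    by_pair: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pair_id, _, tag = rec.id.partition("|")
        if pair_id not in by_pair:
            by_pair[pair_id] = {}
            order.append(pair_id)
        by_pair[pair_id][tag or str(len(by_pair[pair_id]))] = str(rec.seq)
    pairs = []
    for pid in order:
        seqs = list(by_pair[pid].values())
        if len(seqs) != 2:
            raise ValueError(f"{path}: pair {pid} does not have exactly 2 records")
        pairs.append(CodonAlignmentPair(pid, seqs[0], seqs[1]))
    return pairs
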