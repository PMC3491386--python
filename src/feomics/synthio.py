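"""Seeded synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of study input at the study's scale —
two cDNA libraries of ~95,000 reads, promoters with an 8-mer planted
200 bases upstream of the translation start, isotope-pair PSM tables
with decoys, gene trees with controlled sister-clade composition, and
cell-dimension tables spanning the factor-2 growth range of a cylinder
cell — and also returns a machine-readable truth table (the planted
fold changes, ratios, motif positions or verdicts) so downstream
recovery tests never need external data.

Every generator draws from a single numpy Generator seeded from its
spec; identical seeds give bit-identical outputs.

What the generators do *not* emulate: read-level sequencing artifacts
(no FASTQ), count overdispersion beyond the multinomial, spectra (only
match-level records), and assembly structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SynthGenomeSpec",
    "SynthCountSpec",
    "SynthPsmSpec",
    "SynthCellSpec",
    "SynthTreeSpec",
    "GenomeBundle",
    "gen_genome",
    "gen_counts",
    "gen_psms",
    "gen_cells",
    "gen_trees",
]

_BASES = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

COMPARTMENTS = ("nuclear", "chloroplast", "mitochondrial", "rRNA", "other")


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _count_overlapping(s: str, w: str) -> int:
    count = 0
    i = s.find(w)
    while i != -1:
        count += 1
        i = s.find(w, i + 1)
    return count


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


# ---------------------------------------------------------------------------
# genome + gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthGenomeSpec:
    """Synthetic genome: one contig per gene with a configurable promoter.

    ``motif_offset`` places the planted motif's 5' end that many bases
    upstream of the translation start (default 200, the conserved
    position of the iron-regulated promoter element).
    """

    n_genes: int
    motif: str = "ACACGTGC"
    promoter_len: int = 500
    gene_len: int = 900
    motif_offset: int = 200
    planted_gene_ids: frozenset[str] = frozenset()
    compartments: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be at least 1")
        motif = self.motif.upper()
        if not motif or not set(motif) <= set("ACGT"):
            raise ValueError("motif must contain only ACGT")
        object.__setattr__(self, "motif", motif)
        if self.motif_offset + len(motif) > self.promoter_len:
            raise ValueError(
                "motif does not fit the promoter: "
                f"offset {self.motif_offset} + |motif| {len(motif)} "
                f"> promoter_len {self.promoter_len}"
            )
        if self.motif_offset < len(motif):
            raise ValueError("motif_offset must be at least the motif length")
        if self.gene_len < 3:
            raise ValueError("gene_len must cover at least a start codon")
        ids = set(self.gene_ids)
        unknown = set(self.planted_gene_ids) - ids
        if unknown:
            raise ValueError(f"planted ids not among gene ids: {sorted(unknown)[:5]}")
        if self.compartments is not None:
            bad = set(self.compartments.values()) - set(COMPARTMENTS)
            if bad:
                raise ValueError(f"unknown compartments: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(1, self.n_genes + 1)]


@dataclass(frozen=True)
class GenomeBundle:
    records: list[SeqRecord]
    models: pd.DataFrame  # gene_id, contig, start, end, strand
    truth: pd.DataFrame  # gene_id, contig, strand, compartment, planted, motif_offset

    def write_fasta(self, path) -> None:
        from Bio import SeqIO

        SeqIO.write(self.records, str(path), "fasta")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for rec in self.models.itertuples(index=False):
                attrs_gene = f"ID={rec.gene_id}"
                attrs_cds = f"ID=cds_{rec.gene_id};Parent={rec.gene_id};gene_id={rec.gene_id}"
                fh.write(
                    f"{rec.contig}\tsynthio\tgene\t{rec.start}\t{rec.end}\t.\t{rec.strand}\t.\t{attrs_gene}\n"
                )
                fh.write(
                    f"{rec.contig}\tsynthio\tCDS\t{rec.start}\t{rec.end}\t.\t{rec.strand}\t0\t{attrs_cds}\n"
                )


def _make_promoter(rng: np.random.Generator, spec: SynthGenomeSpec, planted: bool) -> str:
    """A promoter window on the coding strand.

    Non-planted promoters are motif-free by rejection sampling; planted
    promoters carry exactly one occurrence, at the configured offset
    (resampled until the insertion creates no second, overlapping or
    distant, occurrence).
    """
    insert_at = spec.promoter_len - spec.motif_offset
    for _ in range(10_000):
        p = _rand_dna(rng, spec.promoter_len)
        if planted:
            p = p[:insert_at] + spec.motif + p[insert_at + len(spec.motif) :]
            if _count_overlapping(p, spec.motif) == 1:
                return p
        else:
            if spec.motif not in p:
                return p
    raise RuntimeError("promoter rejection sampling did not converge")  # pragma: no cover


def gen_genome(spec: SynthGenomeSpec) -> GenomeBundle:
    """Generate contigs and gene models with planted promoter motifs.

    One contig per gene; strand is drawn at random per gene, and for
    minus-strand genes the promoter is laid down as the reverse
    complement of the downstream genomic flank, so the motif always sits
    on the coding strand at the planted upstream offset.
    """
    rng = np.random.default_rng(spec.seed)
    tail_len = 30
    compartments = dict(spec.compartments or {})
    records: list[SeqRecord] = []
    model_rows = []
    truth_rows = []
    for gene_id in spec.gene_ids:
        planted = gene_id in spec.planted_gene_ids
        strand = "+" if rng.random() < 0.5 else "-"
        promoter = _make_promoter(rng, spec, planted)
        gene_body = "ATG" + _rand_dna(rng, spec.gene_len - 3)
        tail = _rand_dna(rng, tail_len)
        contig_id = f"ctg_{gene_id}"
        if strand == "+":
            seq = promoter + gene_body + tail
            start = spec.promoter_len + 1
            end = spec.promoter_len + spec.gene_len
        else:
            seq = tail + _revcomp(gene_body) + _revcomp(promoter)
            start = tail_len + 1
            end = tail_len + spec.gene_len
        records.append(SeqRecord(Seq(seq), id=contig_id, description=""))
        model_rows.append(
            {"gene_id": gene_id, "contig": contig_id, "start": start, "end": end, "strand": strand}
        )
        truth_rows.append(
            {
                "gene_id": gene_id,
                "contig": contig_id,
                "strand": strand,
                "compartment": compartments.get(gene_id, "nuclear"),
                "planted": planted,
                "motif_offset": spec.motif_offset if planted else 0,
                "seed": spec.seed,
            }
        )
    return GenomeBundle(
        records=records,
        models=pd.DataFrame(model_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthCountSpec:
    """Two-library multinomial read counts with planted fold changes.

    Library sizes default to 95,000 reads each (the study scale). Fold
    changes multiply a gene's relative abundance in the Fe(-) library;
    genes without an entry default to 1.0. ``baseline_weights`` maps
    gene id -> relative abundance; None draws lognormal abundances
    (sigma 1), emulating the skewed transcript abundance of an EST
    library.
    """

    library_sizes: tuple[int, int] = (95_000, 95_000)
    baseline_weights: Mapping[str, float] | None = None
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if self.baseline_weights is not None and any(
            w <= 0 for w in self.baseline_weights.values()
        ):
            raise ValueError("baseline weights must be positive")
        if any(f < 0 for f in self.fold_changes.values()):
            raise ValueError("fold changes must be non-negative")


def gen_counts(
    gene_ids: Sequence[str],
    spec: SynthCountSpec,
    compartments: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-gene counts for the Fe(-) and Fe(+) libraries.

    Per library i the counts are one multinomial draw of size N_i with
    per-gene probabilities proportional to the baseline weights (times
    the fold change for the Fe(-) library), so each library's counts sum
    to N_i exactly.

    Returns (counts, truth): counts has columns ``gene_id,
    count_fe_minus, count_fe_plus[, compartment]``; truth records the
    planted weights and fold changes.
    """
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene ids must be unique")
    rng = np.random.default_rng(spec.seed)
    if spec.baseline_weights is None:
        weights = np.exp(rng.normal(0.0, 1.0, size=len(gene_ids)))
    else:
        missing = [g for g in gene_ids if g not in spec.baseline_weights]
        if missing:
            raise ValueError(f"baseline weights missing for genes: {missing[:5]}")
        weights = np.array([spec.baseline_weights[g] for g in gene_ids], dtype=float)
    unknown_fc = set(spec.fold_changes) - set(gene_ids)
    if unknown_fc:
        raise ValueError(f"fold changes for unknown genes: {sorted(unknown_fc)[:5]}")
    n_defaulted = sum(1 for g in gene_ids if g not in spec.fold_changes)
    if spec.fold_changes and n_defaulted:
        logger.info("%d genes without fold change default to 1.0", n_defaulted)
    folds = np.array([spec.fold_changes.get(g, 1.0) for g in gene_ids], dtype=float)

    p_minus = weights * folds
    p_minus = p_minus / p_minus.sum()
    p_plus = weights / weights.sum()
    n_minus, n_plus = spec.library_sizes
    counts = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "count_fe_minus": rng.multinomial(n_minus, p_minus),
            "count_fe_plus": rng.multinomial(n_plus, p_plus),
        }
    )
    if compartments is not None:
        counts["compartment"] = [compartments.get(g, "nuclear") for g in gene_ids]
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_weight": weights,
            "fold_change": folds,
            "seed": spec.seed,
        }
    )
    return counts, truth


# ---------------------------------------------------------------------------
# peptide-spectrum matches
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthPsmSpec:
    """Isotope-pair PSM records with planted per-protein Fe(-)/Fe(+) ratios.

    Each protein contributes ``n_pbc_per_protein`` distinct
    (peptide, band, charge) combinations whose light/heavy intensity
    pair is lognormal around the planted ratio with coefficient of
    variation ``intensity_cv``. Decoy records are drawn with E-values
    stochastically above the targets' so FDR thresholding is
    informative; target E-values are log-uniform over
    ``10**target_log10_evalue``, decoys over ``10**decoy_log10_evalue``.
    """

    proteins: tuple[tuple[str, tuple[str, ...]], ...] | None = None
    true_ratios: Mapping[str, float] = field(default_factory=dict)
    n_proteins: int = 20
    n_pbc_per_protein: int = 5
    decoy_fraction: float = 0.1
    target_log10_evalue: tuple[float, float] = (-12.0, -4.0)
    decoy_log10_evalue: tuple[float, float] = (-3.0, 0.0)
    ppm_noise_sd: float = 1.5
    intensity_cv: float = 0.1
    heavy_condition: Literal["fe_plus", "fe_minus"] = "fe_plus"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")
        if any(r <= 0 for r in self.true_ratios.values()):
            raise ValueError("true ratios must be positive")
        if self.n_pbc_per_protein < 1:
            raise ValueError("n_pbc_per_protein must be at least 1")
        if self.intensity_cv < 0 or self.ppm_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")


def _rand_peptide(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        pep = "".join(_AA[rng.integers(0, len(_AA), size=int(rng.integers(8, 15)))])
        if pep not in used:
            used.add(pep)
            return pep


def gen_psms(spec: SynthPsmSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a PSM table and the planted-ratio truth table."""
    rng = np.random.default_rng(spec.seed)
    used_peptides: set[str] = set()
    if spec.proteins is None:
        proteins = [
            (
                f"prot{i:03d}",
                tuple(_rand_peptide(rng, used_peptides) for _ in range(spec.n_pbc_per_protein)),
            )
            for i in range(1, spec.n_proteins + 1)
        ]
    else:
        proteins = [(pid, tuple(peps)) for pid, peps in spec.proteins]
        for _, peps in proteins:
            used_peptides.update(peps)

    sigma = float(np.sqrt(np.log1p(spec.intensity_cv**2)))
    lo_t, hi_t = spec.target_log10_evalue
    lo_d, hi_d = spec.decoy_log10_evalue
    rows = []
    truth_rows = []
    spectrum = 0
    for pid, peptides in proteins:
        ratio = float(spec.true_ratios.get(pid, 1.0))
        truth_rows.append({"protein_id": pid, "true_ratio": ratio})
        combos: set[tuple[str, int, int]] = set()
        j = 0
        while len(combos) < spec.n_pbc_per_protein:
            pep = peptides[j % len(peptides)]
            band = int(rng.integers(1, 13))
            charge = int(rng.integers(2, 5))
            j += 1
            if (pep, band, charge) in combos:
                continue
            combos.add((pep, band, charge))
            spectrum += 1
            base = float(1e6 * np.exp(rng.normal(0.0, 0.5)))
            pair_ratio = ratio * float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else ratio
            # pair_ratio is Fe(-)/Fe(+); which channel that is depends on labeling
            if spec.heavy_condition == "fe_plus":
                heavy, light = base, base * pair_ratio
            else:
                light, heavy = base, base * pair_ratio
            evalue = float(10.0 ** rng.uniform(lo_t, hi_t))
            rows.append(
                {
                    "spectrum_id": f"spec{spectrum:05d}",
                    "peptide": pep,
                    "protein_ids": pid,
                    "evalue": evalue,
                    "evalue_second_best": evalue * float(10.0 ** rng.uniform(0.5, 3.0)),
                    "ppm_dev": float(rng.normal(0.0, spec.ppm_noise_sd))
                    if spec.ppm_noise_sd > 0
                    else 0.0,
                    "band": band,
                    "charge": charge,
                    "is_decoy": False,
                    "intensity_light": light,
                    "intensity_heavy": heavy,
                }
            )
    n_targets = len(rows)
    n_decoys = int(round(n_targets * spec.decoy_fraction / (1.0 - spec.decoy_fraction)))
    for k in range(1, n_decoys + 1):
        spectrum += 1
        decoy_evalue = float(10.0 ** rng.uniform(lo_d, hi_d))
        rows.append(
            {
                "spectrum_id": f"spec{spectrum:05d}",
                "peptide": _rand_peptide(rng, used_peptides),
                "protein_ids": f"DECOY_{k:03d}",
                "evalue": decoy_evalue,
                "evalue_second_best": decoy_evalue * float(10.0 ** rng.uniform(0.5, 3.0)),
                "ppm_dev": float(rng.normal(0.0, spec.ppm_noise_sd))
                if spec.ppm_noise_sd > 0
                else 0.0,
                "band": int(rng.integers(1, 13)),
                "charge": int(rng.integers(2, 5)),
                "is_decoy": True,
                "intensity_light": float(1e4 * np.exp(rng.normal(0.0, 0.5))),
                "intensity_heavy": float(1e4 * np.exp(rng.normal(0.0, 0.5))),
            }
        )
    psms = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    truth["seed"] = spec.seed
    return psms, truth


# ---------------------------------------------------------------------------
# cell measurements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthCellSpec:
    """Cell dimension measurements over the factor-2 growth range.

    Defaults emulate the study's iron-replete condition: 20 measured
    cells of unit diameter 5.9 µm and unit height 5.5 µm. The cylinder
    grows by height only: lengths span [unit_length, 2 * unit_length]
    either uniformly over growth phase (``uniform_phase``, the default)
    or with the age density 2 ln2 * 2^(-a), a in [0, 1], of an
    exponentially growing population (``exponential_age``). Measurement
    noise is multiplicative lognormal with CV ``noise_cv`` on both
    dimensions.
    """

    n_cells: int = 20
    unit_diameter: float = 5.9
    unit_length: float = 5.5
    growth_model: Literal["uniform_phase", "exponential_age"] = "uniform_phase"
    noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.unit_diameter <= 0 or self.unit_length <= 0:
            raise ValueError("unit dimensions must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def gen_cells(spec: SynthCellSpec) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw per-cell (diameter, length) measurements.

    Returns (measurements, truth) where truth records the planted unit
    dimensions and growth model.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.n_cells)
    if spec.growth_model == "uniform_phase":
        lengths = spec.unit_length * (1.0 + u)
    elif spec.growth_model == "exponential_age":
        age = -np.log2(1.0 - u / 2.0)
        lengths = spec.unit_length * np.exp2(age)
    else:
        raise ValueError(f"unknown growth model {spec.growth_model!r}")
    if spec.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
        diam_noise = np.exp(rng.normal(0.0, sigma, size=spec.n_cells))
        len_noise = np.exp(rng.normal(0.0, sigma, size=spec.n_cells))
    else:
        diam_noise = len_noise = np.ones(spec.n_cells)
    df = pd.DataFrame(
        {
            "cell_id": [f"cell{i:03d}" for i in range(1, spec.n_cells + 1)],
            "diameter_um": spec.unit_diameter * diam_noise,
            "length_um": lengths * len_noise,
        }
    )
    truth = {
        "unit_diameter": spec.unit_diameter,
        "unit_length": spec.unit_length,
        "growth_model": spec.growth_model,
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
    }
    return df, truth


# ---------------------------------------------------------------------------
# gene trees with controlled sister composition
# ---------------------------------------------------------------------------

STRAMENOPILE_TAXA = (
    "Toceanica",
    "Tpseudonana",
    "Ptricornutum",
    "Fcylindrus",
    "Aanophagefferens",
)
NONSTRAMENOPILE_TAXA = (
    ("Micromonas", "green alga"),
    ("Ostreococcus", "green alga"),
    ("Chlamydomonas", "green alga"),
    ("Synechococcus", "cyanobacterium"),
    ("Ecoli", "proteobacterium"),
    ("Bsubtilis", "firmicute"),
    ("Rhodobacter", "proteobacterium"),
)


@dataclass(frozen=True)
class SynthTreeSpec:
    """Gene trees with planted sister-clade verdicts.

    Defaults mirror the study's tally of refined phylogenies: 180
    lateral-transfer topologies, 10 vertical and 8 with a mixed sister
    clade, for 198 trees total. Queries are leaves of the focal
    stramenopile species; a fraction of trees carries a conspecific
    paralog next to the query.
    """

    n_lgt: int = 180
    n_vertical: int = 10
    n_mixed: int = 8
    paralog_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lgt, self.n_vertical, self.n_mixed) < 0:
            raise ValueError("tree counts must be non-negative")
        if not 0 <= self.paralog_fraction <= 1:
            raise ValueError("paralog_fraction must be in [0, 1]")


def lineage_table() -> pd.DataFrame:
    """The taxon -> lineage map covering all generated leaf taxa."""
    rows = [{"taxon": t, "group": "stramenopile", "stramenopile": 1} for t in STRAMENOPILE_TAXA]
    rows += [{"taxon": t, "group": g, "stramenopile": 0} for t, g in NONSTRAMENOPILE_TAXA]
    return pd.DataFrame(rows)


def gen_trees(spec: SynthTreeSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate newick gene trees with known sister-clade composition.

    Returns (trees, lineages): trees has columns ``tree_id, query_leaf,
    newick, true_verdict``; lineages is the matching taxon map. Branch
    lengths are chosen so that midpoint rooting separates the query-side
    clade from the far pair, leaving the planted sister intact.
    """
    rng = np.random.default_rng(spec.seed)
    query_species = STRAMENOPILE_TAXA[0]
    other_stram = list(STRAMENOPILE_TAXA[1:])
    nonstram = [t for t, _ in NONSTRAMENOPILE_TAXA]
    rows = []
    kinds = (
        ["lgt_confirmed"] * spec.n_lgt
        + ["vertical"] * spec.n_vertical
        + ["unresolved"] * spec.n_mixed
    )
    for i, kind in enumerate(kinds, start=1):
        tid = f"t{i:04d}"
        q = f"{query_species}_{tid}"
        # branch lengths: every query-side leaf sits 1.1 below the query-side
        # top node, far leaves 1.0 below theirs; the midpoint of the longest
        # path (3.1) then falls strictly inside the central edge, preserving
        # the planted bipartition under midpoint rooting
        if rng.random() < spec.paralog_fraction:
            q_clade = f"({q}:0.3,{query_species}_{tid}p:0.3):0.8"
        else:
            q_clade = f"{q}:1.1"
        if kind == "lgt_confirmed":
            far1, far2 = rng.choice(other_stram, 2, replace=False)
            donors = rng.choice(nonstram, int(rng.integers(1, 3)), replace=False)
            if len(donors) == 1:
                sister = f"{donors[0]}_{tid}:1.1"
            else:
                sister = f"({donors[0]}_{tid}:0.6,{donors[1]}_{tid}:0.6):0.5"
            newick = f"(({q_clade},{sister}):0.5,({far1}_{tid}:1.0,{far2}_{tid}:1.0):0.5);"
        elif kind == "vertical":
            far1, far2 = rng.choice(nonstram, 2, replace=False)
            sis = rng.choice(other_stram)
            newick = f"(({q_clade},{sis}_{tid}:1.1):0.5,({far1}_{tid}:1.0,{far2}_{tid}:1.0):0.5);"
        else:  # mixed sister: one stramenopile plus one foreign taxon
            s = rng.choice(other_stram)
            ns, far1, far2 = rng.choice(nonstram, 3, replace=False)
            sister = f"({s}_{tid}:0.6,{ns}_{tid}:0.6):0.5"
            newick = f"(({q_clade},{sister}):0.5,({far1}_{tid}:1.0,{far2}_{tid}:1.0):0.5);"
        rows.append(
            {"tree_id": tid, "query_leaf": q, "newick": newick, "true_verdict": kind, "seed": spec.seed}
        )
    return pd.DataFrame(rows), lineage_table()
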