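"""Positional promoter motif screening relative to the translation start.

Promoter windows are the upstream flank of each gene read 5'->3' on the
gene's coding strand, anchored at the translation start (first base of
the start codon). An occurrence offset of ``n`` means the motif's 5' end
sits ``n`` bases before the start codon, i.e. the motif occupies
positions -n .. -n+|motif|-1. A genome-wide screen reports perfect
(exact-string) matches whose offset falls in an inclusive window —
the iron-regulated promoter element studied here, the E-box-like 8-mer
ACACGTGC with CACGTG core, sits around offset 200 and is screened in the
window [150, 250].

A conserved-positional-k-mer finder generalizes this: it reports k-mers
shared by a set of promoters (e.g. orthologous promoters from several
species) whose occurrences cluster around a common offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "MotifReport",
    "read_gene_models",
    "extract_promoters",
    "scan_motif",
    "find_conserved_positional_kmers",
    "motif_report",
]

_DNA = set("ACGT")


def _require_dna(motif: str) -> str:
    motif = motif.upper()
    if not motif or not set(motif) <= _DNA:
        raise ValueError(f"motif must be a non-empty ACGT string, got {motif!r}")
    return motif


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


# ---------------------------------------------------------------------------
# gene models and promoter extraction
# ---------------------------------------------------------------------------


def read_gene_models(gff_path) -> pd.DataFrame:
    """Gene models from a GFF3 file (1-based closed CDS intervals).

    Returns a DataFrame with ``gene_id, contig, start, end, strand``, one
    row per gene, using each gene's CDS span; the translation start is
    the first CDS base (``start`` on +, ``end`` on -). Malformed lines
    raise with the file and line number.
    """
    import gffutils

    gff_path = str(gff_path)
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"{gff_path}:{lineno}: malformed GFF3 line (expected 9 columns)")
    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("gene_id", feat.attributes.get("Parent", [feat.id]))[0]
        rows.append(
            {
                "gene_id": gene_id,
                "contig": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    if not rows:
        raise ValueError(f"{gff_path}: no CDS features found")
    return pd.DataFrame(rows)


def extract_promoters(
    genome,
    gene_models: pd.DataFrame,
    upstream_len: int = 500,
) -> pd.DataFrame:
    """Upstream windows on the coding strand for every gene model.

    Parameters
    ----------
    genome : FASTA path or a mapping contig -> sequence string.
    gene_models : DataFrame with ``gene_id, contig, start, end, strand``
        (1-based closed coordinates; translation start = first CDS base).
    upstream_len : window length in bases.

    Returns
    -------
    DataFrame ``gene_id, sequence, strand, truncated``; for + genes the
    window is the genomic flank 5' of the start codon, for - genes the
    reverse complement of the downstream genomic flank. Genes at a contig
    edge get a truncated window flagged ``truncated=True``, never dropped.
    """
    if upstream_len <= 0:
        raise ValueError("upstream_len must be positive")
    if isinstance(genome, (str,)) or hasattr(genome, "__fspath__"):
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}
    else:
        seqs = {k: str(v).upper() for k, v in dict(genome).items()}
    rows = []
    for rec in gene_models.itertuples(index=False):
        if rec.contig not in seqs:
            raise ValueError(f"gene {rec.gene_id}: contig {rec.contig!r} not in genome")
        contig = seqs[rec.contig]
        if not (1 <= rec.start <= rec.end <= len(contig)):
            raise ValueError(f"gene {rec.gene_id}: CDS outside contig bounds")
        if rec.strand == "+":
            lo = max(0, rec.start - 1 - upstream_len)
            window = contig[lo : rec.start - 1]
        elif rec.strand == "-":
            window = _revcomp(contig[rec.end : rec.end + upstream_len])
        else:
            raise ValueError(f"gene {rec.gene_id}: bad strand {rec.strand!r}")
        rows.append(
            {
                "gene_id": rec.gene_id,
                "sequence": window,
                "strand": rec.strand,
                "truncated": len(window) < upstream_len,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------


def _occurrence_offsets(promoter: str, motif: str) -> list[int]:
    """Offsets (bases upstream of the anchor) of all, possibly overlapping,
    exact occurrences of `motif` in a promoter string.

    The promoter's last character sits at position -1; a motif whose
    5' end is at string index i has offset len(promoter) - i.
    """
    offsets = []
    i = promoter.find(motif)
    while i != -1:
        offsets.append(len(promoter) - i)
        i = promoter.find(motif, i + 1)
    return offsets


def scan_motif(
    promoters: pd.DataFrame,
    motif: str,
    window: tuple[int, int] = (150, 250),
    both_strands: bool = False,
) -> pd.DataFrame:
    """Perfect-match screen of a motif over promoter windows.

    A hit is reported when the motif's 5'-end offset lies in the
    inclusive ``window``; multiple hits per gene are all reported.
    Matching is on the coding strand only unless ``both_strands`` is set
    (the reverse complement is then also searched and flagged). Window
    positions containing non-ACGT characters never match.
    """
    motif = _require_dna(motif)
    lo, hi = window
    if not (0 < lo <= hi):
        raise ValueError("window bounds must satisfy 0 < lo <= hi")
    queries = [(motif, "+")]
    if both_strands:
        rc = _revcomp(motif)
        if rc != motif:
            queries.append((rc, "-"))
    rows = []
    for rec in promoters.itertuples(index=False):
        for query, mstrand in queries:
            for off in _occurrence_offsets(rec.sequence.upper(), query):
                if lo <= off <= hi:
                    rows.append(
                        {
                            "gene_id": rec.gene_id,
                            "offset": off,
                            "strand_of_gene": rec.strand,
                            "motif_strand": mstrand,
                        }
                    )
    return pd.DataFrame(rows, columns=["gene_id", "offset", "strand_of_gene", "motif_strand"])


def find_conserved_positional_kmers(
    promoters: list[str],
    k: int,
    window: tuple[int, int] = (150, 250),
    position_tolerance: int = 50,
) -> pd.DataFrame:
    """Exact k-mers shared by all promoters at a conserved position.

    A k-mer is reported when some integer center ``c`` inside the
    inclusive ``window`` exists such that every promoter has at least one
    occurrence whose offset is within ``position_tolerance`` of ``c``.
    Reported k-mers carry the best feasible center and the positional
    spread (the smallest achievable maximum deviation from the center)
    and are ranked by spread ascending, ties broken lexicographically.

    This is a defined exact-match stand-in for probabilistic motif
    discovery over orthologous promoters.
    """
    if len(promoters) < 2:
        raise ValueError("at least two promoters are required")
    if k <= 0 or k > min(len(p) for p in promoters):
        raise ValueError("k must be positive and no longer than the shortest promoter")
    lo, hi = window
    offset_maps: list[dict[str, list[int]]] = []
    for p in promoters:
        p = p.upper()
        m: dict[str, list[int]] = {}
        for i in range(len(p) - k + 1):
            w = p[i : i + k]
            if set(w) <= _DNA:
                m.setdefault(w, []).append(len(p) - i)
        offset_maps.append(m)
    shared = set(offset_maps[0])
    for m in offset_maps[1:]:
        shared &= set(m)
    rows = []
    for w in sorted(shared):
        best_spread = None
        best_center = None
        for c in range(lo, hi + 1):
            devs = []
            feasible = True
            for m in offset_maps:
                d = min(abs(o - c) for o in m[w])
                if d > position_tolerance:
                    feasible = False
                    break
                devs.append(d)
            if feasible:
                spread = max(devs)
                if best_spread is None or spread < best_spread:
                    best_spread, best_center = spread, c
        if best_spread is not None:
            rows.append({"motif": w, "center": best_center, "spread": best_spread})
    out = pd.DataFrame(rows, columns=["motif", "center", "spread"])
    return out.sort_values(["spread", "motif"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# motif description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifReport:
    """Base composition and longest self-reverse-complementary core of a motif."""

    motif: str
    composition: dict[str, int]
    core_palindrome: str

    @property
    def is_full_palindrome(self) -> bool:
        return self.core_palindrome == self.motif


def motif_report(motif: str) -> MotifReport:
    """Composition and longest reverse-complement-palindromic core substring.

    A DNA palindrome reads the same as its reverse complement (so it has
    even length); among equally long cores the leftmost is reported. The
    iron-regulated 8-mer ACACGTGC, for instance, is not itself a
    palindrome but contains the canonical E-box core CACGTG, which is.
    """
    motif = _require_dna(motif)
    composition = {b: motif.count(b) for b in "ACGT"}
    core = ""
    for length in range(len(motif), 0, -1):
        for start in range(0, len(motif) - length + 1):
            sub = motif[start : start + length]
            if sub == _revcomp(sub):
                core = sub
                break
        if core:
            break
    return MotifReport(motif=motif, composition=composition, core_palindrome=core)
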