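"""Genome-wide smORF discovery.

Both strands of every contig are scanned in all three frames for spans
running from a configured start codon (ATG plus the near-cognate set CTG,
GTG, ACG, TTG, ATT, ATC, ATA, AAG, AGG) to the nearest in-frame stop, with a
codon count (stop included) between 11 and 101 by default.  Candidates are
scored by a trained coding-potential model and filtered with per-start-codon
cutoffs: near-cognate starts initiate less efficiently, so rarer ones must
clear a stricter score bar, and the weakest (AAG, AGG) are excluded outright.
Candidates wholly inside an annotated same-strand CDS exon are then removed
and the survivors written out as a FASTA / BED6 / TSV database.

Coordinates are 0-based half-open on the forward strand throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio.Seq import Seq

from .model_eval import TrainedModel
from .seqdata import CdsIntervalSet, Dataset, OrfRecord, STOP_CODONS, _open_gff_db

logger = logging.getLogger("smorfkit")

#: start codons scanned by default, by reported initiation efficiency rank
DEFAULT_START_CODONS = ("ATG", "CTG", "GTG", "ACG", "TTG",
                        "ATT", "ATC", "ATA", "AAG", "AGG")

#: default per-start-codon score cutoffs; ATG and the rank-1 near-cognate CTG
#: reach precision 0.95 at 0.780, rank-2/3 codons need 0.968 (precision 0.99)
#: or 1.000, and rank-4 codons AAG/AGG are excluded from the map entirely
DEFAULT_CUTOFFS: dict[str, float] = {
    "ATG": 0.780, "CTG": 0.780,
    "GTG": 0.968, "ACG": 0.968,
    "TTG": 1.000, "ATT": 1.000, "ATC": 1.000, "ATA": 1.000,
}

MIN_SCAN_CODONS = 11
MAX_SCAN_CODONS = 101


@dataclass
class GenomeCandidate:
    chrom: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str  # {+, -}
    frame: int  # reading-strand frame {0, 1, 2}
    start_codon: str
    upstream3: str  # strand-aware genomic context, N-padded at contig edges
    orf_seq: str  # sense-strand sequence, start through stop codon
    score: float = float("nan")
    overlap_gene: Optional[str] = None
    overlap_type: str = "none"

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    @property
    def n_codons(self) -> int:
        return len(self.orf_seq) // 3

    def to_orf_record(self) -> OrfRecord:
        return OrfRecord(id=self.id, upstream3=self.upstream3,
                         orf_seq=self.orf_seq, start_codon=self.start_codon,
                         label="unknown", source="genomescan")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _contigs(genome) -> Iterator[tuple[str, str]]:
    """Accept a FASTA path, a pyfaidx.Fasta, or a {name: sequence} mapping."""
    if isinstance(genome, dict):
        for name, seq in genome.items():
            yield name, str(seq).upper()
        return
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta
        fa = Fasta(str(genome), rebuild=True)
        for name in fa.keys():
            yield name, str(fa[name][:]).upper()
        return
    for name in genome.keys():  # pyfaidx.Fasta or similar mapping
        yield name, str(genome[name][:]).upper()


def _scan_reading_strand(seq: str, start_codons: frozenset[str],
                         min_codons: int, max_codons: int,
                         longest_only: bool) -> Iterator[tuple[int, int, int]]:
    """Yield (start, end, frame) on the reading strand, half-open."""
    n = len(seq)
    for frame in range(3):
        open_starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                qualifying = [s for s in open_starts
                              if min_codons <= (i + 3 - s) // 3 <= max_codons]
                if longest_only:
                    qualifying = qualifying[:1]  # 5'-most start for this stop
                for s in qualifying:
                    yield s, i + 3, frame
                open_starts.clear()
            elif codon in start_codons:
                open_starts.append(i)


def scan_smorfs(genome, start_codons: Iterable[str] = DEFAULT_START_CODONS,
                min_codons: int = MIN_SCAN_CODONS,
                max_codons: int = MAX_SCAN_CODONS,
                longest_only: bool = False) -> Iterator[GenomeCandidate]:
    """Enumerate unscored smORF candidates over both strands of a genome.

    Every qualifying start upstream of a shared in-frame stop yields its own
    candidate unless ``longest_only`` collapses to the 5'-most start per
    (stop, frame, strand).  Codons containing ambiguity codes are never
    starts or stops, and candidates containing N in the ORF are discarded.
    The upstream context is read strand-aware and N-padded at contig edges.
    """
    if not 2 <= min_codons <= max_codons:
        raise ValueError("need 2 <= min_codons <= max_codons")
    starts = frozenset(c.upper() for c in start_codons)
    for chrom, fwd in _contigs(genome):
        rev = str(Seq(fwd).reverse_complement())
        n = len(fwd)
        for strand, seq in (("+", fwd), ("-", rev)):
            for s, e, frame in _scan_reading_strand(seq, starts, min_codons,
                                                    max_codons, longest_only):
                orf = seq[s:e]
                if "N" in orf:
                    continue
                upstream = ("N" * 3 + seq)[s:s + 3]
                if strand == "+":
                    g_start, g_end = s, e
                else:
                    g_start, g_end = n - e, n - s
                yield GenomeCandidate(chrom=chrom, start=g_start, end=g_end,
                                      strand=strand, frame=frame,
                                      start_codon=orf[:3], upstream3=upstream,
                                      orf_seq=orf)


# ---------------------------------------------------------------------------
# scoring and filtering
# ---------------------------------------------------------------------------

def score_candidates(candidates: Iterable[GenomeCandidate],
                     model: TrainedModel) -> list[GenomeCandidate]:
    """Attach model scores (positive-class probability) to candidates."""
    cands = list(candidates)
    if not cands:
        return []
    records = Dataset([c.to_orf_record() for c in cands])
    from .model_eval import predict_scores
    scores = predict_scores(model, records)
    return [replace(c, score=float(s)) for c, s in zip(cands, scores)]


def score_and_filter(candidates: Iterable[GenomeCandidate],
                     model: Optional[TrainedModel] = None,
                     cutoffs: Optional[dict[str, float]] = None
                     ) -> list[GenomeCandidate]:
    """Keep candidates whose score reaches their start codon's cutoff.

    Candidates whose start codon is absent from the cutoff map (AAG/AGG under
    the defaults) are dropped regardless of score.  Unscored candidates are
    scored through ``model`` first.
    """
    cutoffs = DEFAULT_CUTOFFS if cutoffs is None else cutoffs
    if any(not 0 <= v <= 1 for v in cutoffs.values()):
        raise ValueError("cutoffs must be in [0, 1]")
    cands = list(candidates)
    if any(math.isnan(c.score) for c in cands):
        if model is None:
            raise ValueError("unscored candidates and no model given")
        cands = score_candidates(cands, model)
    kept = [c for c in cands
            if c.start_codon in cutoffs and c.score >= cutoffs[c.start_codon]]
    logger.info("score_and_filter: kept %d / %d candidates", len(kept), len(cands))
    return kept


def remove_within_cds(candidates: Iterable[GenomeCandidate],
                      cds: CdsIntervalSet) -> list[GenomeCandidate]:
    """Drop candidates wholly contained in a single same-strand annotated CDS
    interval; partial overlaps and opposite-strand containment are retained."""
    return [c for c in candidates
            if not cds.contains(c.chrom, c.strand, c.start, c.end)]


# ---------------------------------------------------------------------------
# gene-overlap annotation
# ---------------------------------------------------------------------------

_BIOTYPE_PRECEDENCE = {"protein_coding": 0, "lncRNA": 1, "pseudogene": 2,
                       "transcribed_pseudogene": 3, "other": 4}


def _normalize_biotype(raw: Optional[str]) -> str:
    if not raw:
        return "other"
    if raw == "protein_coding":
        return "protein_coding"
    if raw in ("lncRNA", "lincRNA"):
        return "lncRNA"
    if "transcribed" in raw and "pseudogene" in raw:
        return "transcribed_pseudogene"
    if raw.endswith("pseudogene"):
        return "pseudogene"
    return "other"


def load_gene_spans(annotation: str | Path) -> dict[str, list[tuple[int, int, str, str]]]:
    """Per-chromosome gene spans (start, end, name, biotype), 0-based half-open."""
    db = _open_gff_db(annotation)
    spans: dict[str, list[tuple[int, int, str, str]]] = {}
    if db is None:
        return spans
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        raw = (attrs.get("gene_biotype") or attrs.get("biotype")
               or attrs.get("gene_type") or [None])[0]
        name = (attrs.get("Name") or attrs.get("gene_name")
                or attrs.get("gene_id") or [feat.id])[0]
        spans.setdefault(feat.seqid, []).append(
            (feat.start - 1, feat.end, name, _normalize_biotype(raw)))
    for lst in spans.values():
        lst.sort()
    return spans


def annotate_overlap(candidates: Iterable[GenomeCandidate],
                     annotation: str | Path) -> list[GenomeCandidate]:
    """Assign each candidate the biotype of an intersecting gene span, with
    precedence protein_coding > lncRNA > pseudogene > transcribed_pseudogene
    > other; 'none' when no gene overlaps.  Overlap is strand-agnostic."""
    spans = load_gene_spans(annotation)
    out = []
    for c in candidates:
        hits = [(s, e, nm, bt) for s, e, nm, bt in spans.get(c.chrom, [])
                if s < c.end and e > c.start]
        if not hits:
            out.append(replace(c, overlap_gene=None, overlap_type="none"))
            continue
        s, e, nm, bt = min(hits, key=lambda h: (_BIOTYPE_PRECEDENCE[h[3]], h[2]))
        out.append(replace(c, overlap_gene=nm, overlap_type=bt))
    return out


# ---------------------------------------------------------------------------
# output emission
# ---------------------------------------------------------------------------

def emit_database(candidates: Iterable[GenomeCandidate],
                  out_prefix: str | Path) -> dict[str, Path]:
    """Write the smORF database: ``<prefix>.fa`` (nucleotide sequences),
    ``<prefix>.bed`` (BED6, score = round(1000 * model score)) and
    ``<prefix>.tsv`` (id, upstream3, start_codon, score, overlap columns).
    Output order is (chrom, start, end, strand)."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    cands = sorted(candidates, key=lambda c: (c.chrom, c.start, c.end, c.strand))
    paths = {"fasta": out_prefix.with_suffix(".fa"),
             "bed": out_prefix.with_suffix(".bed"),
             "tsv": out_prefix.with_suffix(".tsv")}
    with open(paths["fasta"], "w") as fa:
        for c in cands:
            fa.write(f">{c.id}\n{c.orf_seq}\n")
    with open(paths["bed"], "w") as bed:
        for c in cands:
            score = 0 if math.isnan(c.score) else round(1000 * c.score)
            bed.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.id}\t{score}\t{c.strand}\n")
    with open(paths["tsv"], "w") as tsv:
        tsv.write("id\tupstream3\tstart_codon\tscore\toverlap_gene\toverlap_type\n")
        for c in cands:
            score = "" if math.isnan(c.score) else f"{c.score:.6g}"
            tsv.write(f"{c.id}\t{c.upstream3}\t{c.start_codon}\t{score}\t"
                      f"{c.overlap_gene or '.'}\t{c.overlap_type}\n")
    return paths


def translate_seps(candidates: Iterable[GenomeCandidate | OrfRecord]) -> list[str]:
    """Translate ORFs to peptides (SEPs): standard code, stop trimmed, and the
    first residue forced to methionine for every start codon — near-cognate
    starts are decoded by the initiator Met-tRNA."""
    out = []
    for c in candidates:
        aa = str(Seq(c.orf_seq).translate())
        if "*" in aa[:-1] or not aa.endswith("*"):
            raise ValueError(f"ORF {getattr(c, 'id', '?')} is not a clean "
                             "start-to-stop span")
        out.append("M" + aa[1:-1])
    return out


def standardized_ratio(S_i: float, P_i: float, S_anno: float, P_anno: float) -> float:
    """Category enrichment of SEPs relative to canonical proteins:
    (S_i / P_i) * (P_anno / S_anno), where S_i/P_i are per-category counts and
    S_anno/P_anno the total annotated counts."""
    if P_i <= 0 or S_anno <= 0:
        raise ValueError("P_i and S_anno must be positive")
    return (S_i / P_i) * (P_anno / S_anno)
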