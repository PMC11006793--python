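"""Sequence dataset handling for smORF coding-potential models.

A training example is an ORF nucleotide sequence (start codon through stop
codon, inclusive) prefixed by the three genomic nucleotides immediately
upstream of the start codon (sites -3, -2, -1 of the translation-initiation
context).  Positives come from annotated mRNA coding sequences; negatives are
the maximal ATG-initiated ORFs extracted from noncoding transcripts.

Coordinates are 0-based half-open internally; GFF3/GTF (1-based closed) are
converted on read and BED is written 0-based half-open.
"""

from __future__ import annotations

import bisect
import logging
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("smorfkit")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NUCLEOTIDES = "ACGT"
#: default bounds, codon counts INCLUDE the terminal stop codon
MIN_CODONS = 2
MAX_CODONS = 101
DEFAULT_SEED = 42


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfRecord:
    """One ORF with its 3-nt upstream context.

    ``orf_seq`` runs from the start codon through the stop codon; its length is
    a multiple of 3 and its codon count (stop included) lies in
    [``MIN_CODONS``, ``MAX_CODONS``] for a valid training record.
    """

    id: str
    upstream3: str
    orf_seq: str
    start_codon: str
    label: str = "unknown"  # {positive, negative, unknown}
    source: str = ""

    @property
    def n_codons(self) -> int:
        return len(self.orf_seq) // 3

    def codons(self) -> list[str]:
        return [self.orf_seq[i:i + 3] for i in range(0, len(self.orf_seq), 3)]

    def problems(self, max_codons: int = MAX_CODONS) -> list[str]:
        """Invariant violations, empty when the record is valid."""
        out = []
        if len(self.upstream3) != 3:
            out.append("upstream3 length != 3")
        if set(self.upstream3) - set(NUCLEOTIDES + "N"):
            out.append("upstream3 has non-ACGTN letters")
        if len(self.orf_seq) % 3 != 0:
            out.append("orf_seq length not divisible by 3")
        else:
            n = self.n_codons
            if not MIN_CODONS <= n <= max_codons:
                out.append(f"codon count {n} outside [{MIN_CODONS}, {max_codons}]")
            if self.orf_seq[-3:] not in STOP_CODONS:
                out.append("last codon is not a stop codon")
            if any(c in STOP_CODONS for c in self.codons()[:-1]):
                out.append("internal in-frame stop codon")
        if not self.orf_seq.startswith(self.start_codon) or len(self.start_codon) != 3:
            out.append("orf_seq does not begin with start_codon")
        return out

    def is_valid(self, max_codons: int = MAX_CODONS) -> bool:
        return not self.problems(max_codons)


@dataclass
class Dataset:
    records: list[OrfRecord] = field(default_factory=list)
    split_tag: str = "unsplit"  # {train, test, unsplit}

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("Dataset ids are not unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def with_label(self, label: str) -> "Dataset":
        return Dataset([replace(r, label=label) for r in self.records], self.split_tag)


class CdsIntervalSet:
    """Per-chromosome, per-strand interval store with O(log n) containment.

    Intervals are 0-based half-open.  ``contains(chrom, strand, start, end)``
    answers whether [start, end) lies entirely within any single stored
    interval on that chromosome and strand — the operative rule for removing
    genome-scan candidates inside canonical CDS exons.
    """

    def __init__(self) -> None:
        self._raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
        self._index: dict[tuple[str, str], tuple[list[int], list[int]]] | None = None

    def add(self, chrom: str, strand: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"empty interval ({start}, {end})")
        self._raw.setdefault((chrom, strand), []).append((start, end))
        self._index = None

    def _build(self) -> dict[tuple[str, str], tuple[list[int], list[int]]]:
        if self._index is None:
            self._index = {}
            for key, ivals in self._raw.items():
                ivals = sorted(ivals)
                starts = [s for s, _ in ivals]
                # prefix max of ends: all intervals left of an index start at or
                # before it, so containment reduces to a prefix-max lookup
                maxend, ends = 0, []
                for _, e in ivals:
                    maxend = max(maxend, e)
                    ends.append(maxend)
                self._index[key] = (starts, ends)
        return self._index

    def contains(self, chrom: str, strand: str, start: int, end: int) -> bool:
        idx = self._build().get((chrom, strand))
        if idx is None:
            return False
        starts, prefix_max_end = idx
        i = bisect.bisect_right(starts, start) - 1
        return i >= 0 and prefix_max_end[i] >= end

    def intervals(self, chrom: str, strand: str) -> list[tuple[int, int]]:
        return sorted(self._raw.get((chrom, strand), []))

    def __len__(self) -> int:
        return sum(len(v) for v in self._raw.values())


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_orf_fasta(path: str | Path, label: str = "unknown",
                   max_codons: int = MAX_CODONS) -> Dataset:
    """Read a FASTA of ``3 upstream nt + ORF`` entries into a Dataset.

    Entries violating the OrfRecord invariants (length not 3+3k, missing stop,
    internal stop, ...) are skipped; the skip count is logged.
    """
    path = Path(path)
    records, skipped = [], 0
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise ValueError(f"no FASTA entries in {path}")
    for entry in entries:
        seq = str(entry.seq).upper()
        if len(seq) < 9 or (len(seq) - 3) % 3 != 0:
            skipped += 1
            continue
        rec = OrfRecord(id=entry.id, upstream3=seq[:3], orf_seq=seq[3:],
                        start_codon=seq[3:6], label=label, source=str(path))
        if not rec.is_valid(max_codons):
            skipped += 1
            continue
        records.append(rec)
    if skipped:
        logger.info("read_orf_fasta: skipped %d invalid entries from %s", skipped, path)
    ds = Dataset(records)
    ds.skipped = skipped  # type: ignore[attr-defined]
    return ds


def write_orf_fasta(dataset: Dataset, path: str | Path) -> None:
    """Inverse of :func:`read_orf_fasta`: upstream3 + orf_seq per entry."""
    recs = [SeqRecord(Seq(r.upstream3 + r.orf_seq), id=r.id, description="")
            for r in dataset]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# ORF derivation from transcripts
# ---------------------------------------------------------------------------

def extract_max_orf(transcript: str, transcript_id: str = "orf",
                    label: str = "unknown") -> Optional[OrfRecord]:
    """Longest ATG-initiated, stop-terminated ORF over the three forward frames.

    The upstream context is the 3 nt preceding the ATG, 'N'-padded when the ORF
    starts within the first three bases.  Length ties break to the 5'-most ORF.
    Returns None when no complete ORF exists.  No length ceiling is applied
    here; filter afterwards when assembling a smORF training set.
    """
    seq = transcript.upper()
    best: tuple[int, int] | None = None  # (start, end), maximizing end-start
    for frame in range(3):
        start_at: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if start_at is None:
                if codon == "ATG":
                    start_at = i
            elif codon in STOP_CODONS:
                span = (start_at, i + 3)
                if best is None or (span[1] - span[0], -span[0]) > (best[1] - best[0], -best[0]):
                    best = span
                start_at = None
    if best is None:
        return None
    s, e = best
    upstream = ("N" * 3 + seq)[s:s + 3]  # 3 nt before s, N-padded at the 5' edge
    return OrfRecord(id=transcript_id, upstream3=upstream, orf_seq=seq[s:e],
                     start_codon="ATG", label=label, source="extract_max_orf")


def derive_negatives(transcripts: Iterable[tuple[str, str]],
                     max_codons: int = MAX_CODONS) -> Dataset:
    """Maximal ORFs from noncoding transcripts, kept when <= max_codons codons."""
    out = []
    for tid, seq in transcripts:
        rec = extract_max_orf(seq, transcript_id=tid, label="negative")
        if rec is not None and rec.is_valid(max_codons):
            out.append(rec)
    return Dataset(out)


# ---------------------------------------------------------------------------
# redundancy removal (CD-HIT-like greedy clustering, exact global alignment)
# ---------------------------------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -0.5


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched columns / alignment length."""
    if a == b:
        return 1.0
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / total if total else 0.0


def _redundant_pair(a: str, b: str, identity: float, length_ratio: float) -> bool:
    la, lb = len(a), len(b)
    if min(la, lb) / max(la, lb) < length_ratio:
        return False
    return pairwise_identity(a, b) >= identity


def remove_redundancy(dataset: Dataset, identity: float = 0.9,
                      length_ratio: float = 0.9) -> Dataset:
    """Greedy longest-first clustering; drop records redundant with a retained
    representative (identity >= cutoff AND shorter/longer >= length_ratio).

    Deterministic: equal lengths tie-break on ascending id.  Idempotent.
    """
    if not 0 < identity <= 1 or not 0 < length_ratio <= 1:
        raise ValueError("identity and length_ratio must be in (0, 1]")
    order = sorted(dataset.records, key=lambda r: (-len(r.orf_seq), r.id))
    kept: list[OrfRecord] = []
    for rec in order:
        seq = rec.upstream3 + rec.orf_seq
        if any(_redundant_pair(seq, k.upstream3 + k.orf_seq, identity, length_ratio)
               for k in kept):
            continue
        kept.append(rec)
    kept_ids = {r.id for r in kept}
    return Dataset([r for r in dataset.records if r.id in kept_ids], dataset.split_tag)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def assemble_datasets(pos: Dataset, neg: Dataset, seed: int = DEFAULT_SEED,
                      train_fraction: float = 2 / 3,
                      balance: bool = True,
                      identity: float = 0.9,
                      length_ratio: float = 0.9,
                      min_per_label: int = 10) -> tuple[Dataset, Dataset]:
    """Balanced per-label 2:1 train:test split with cross-split deduplication.

    The larger class is randomly downsampled to the smaller when ``balance``.
    Test records redundant with any same-label train record (same identity /
    length-ratio rule as :func:`remove_redundancy`) are dropped from the test
    split.  Reproducible under ``seed``.
    """
    rng = random.Random(seed)
    pos_records = [replace(r, label="positive") for r in pos]
    neg_records = [replace(r, label="negative") for r in neg]
    if balance:
        n = min(len(pos_records), len(neg_records))
        pos_records = rng.sample(pos_records, n) if len(pos_records) > n else pos_records
        neg_records = rng.sample(neg_records, n) if len(neg_records) > n else neg_records
    train, test = [], []
    for records in (pos_records, neg_records):
        if len(records) < min_per_label:
            raise ValueError(f"need at least {min_per_label} records per label "
                             "(downstream k-fold CV)")
        shuffled = sorted(records, key=lambda r: r.id)
        rng.shuffle(shuffled)
        n_train = round(len(shuffled) * train_fraction)
        train.extend(shuffled[:n_train])
        test_part = shuffled[n_train:]
        train_seqs = [(r.label, r.upstream3 + r.orf_seq) for r in shuffled[:n_train]]
        for r in test_part:
            seq = r.upstream3 + r.orf_seq
            if any(lab == r.label and _redundant_pair(seq, ts, identity, length_ratio)
                   for lab, ts in train_seqs):
                logger.info("assemble_datasets: dropped test record %s "
                            "(redundant with train)", r.id)
                continue
            test.append(r)
    return Dataset(train, "train"), Dataset(test, "test")


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def _open_gff_db(path: str | Path):
    """In-memory gffutils db, or None for an annotation with no features."""
    import gffutils
    try:
        return gffutils.create_db(str(path), ":memory:", force=True,
                                  merge_strategy="create_unique",
                                  keep_order=True, disable_infer_genes=True,
                                  disable_infer_transcripts=True)
    except gffutils.exceptions.EmptyInputError:
        logger.warning("annotation %s has no features", path)
        return None


def read_cds_intervals(path: str | Path) -> CdsIntervalSet:
    """All CDS feature intervals from a GFF3 or GTF file, 0-based half-open,
    grouped by chromosome and strand.  Empty set (with a warning) when the
    annotation has no CDS features."""
    db = _open_gff_db(path)
    out = CdsIntervalSet()
    n = 0
    for feat in (db.features_of_type("CDS") if db is not None else ()):
        out.add(feat.seqid, feat.strand, feat.start - 1, feat.end)
        n += 1
    if n == 0:
        logger.warning("read_cds_intervals: no CDS features in %s", path)
    return out
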