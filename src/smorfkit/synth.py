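"""Synthetic training sets and toy genomes with planted smORFs.

The training-set generator emulates the contrasts observed between real mRNA
smORFs and ncRNA ORFs: positives carry a skewed synonymous-codon usage and a
Kozak-like initiation context (purine enriched at -3, C at -1, G at +4),
negatives are uniform-codon ORFs with a uniform context.  Both knobs are
mixing weights in [0, 1]; at strength 0 positives and negatives are drawn
from identical distributions (a proper null), at strength 1 the bias is
maximal.  The toy-genome generator plants ORFs at known coordinates with a
guarantee of no accidental in-frame stop inside any planted ORF, plus decoy
CDS annotation for exercising the CDS-containment filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqdata import Dataset, OrfRecord, STOP_CODONS, NUCLEOTIDES
from .features import CODONS, CODON_TO_AA

NONSTOP_CODONS = [c for c in CODONS if c not in STOP_CODONS]
STOPS = sorted(STOP_CODONS)


@dataclass(frozen=True)
class SynthConfig:
    n_pos: int = 500
    n_neg: int = 500
    codon_bias_strength: float = 1.0
    tis_bias_strength: float = 1.0
    length_range: tuple[int, int] = (11, 101)  # codons, stop included
    seed: int = 42

    def validate(self) -> None:
        for s in (self.codon_bias_strength, self.tis_bias_strength):
            if not 0 <= s <= 1:
                raise ValueError("bias strengths must be in [0, 1]")
        lo, hi = self.length_range
        if not (2 <= lo <= hi <= 101):
            raise ValueError("length_range must lie within [2, 101]")


# ---------------------------------------------------------------------------
# codon and context distributions
# ---------------------------------------------------------------------------

def _preferred_codons() -> set[str]:
    """One designated preferred codon per synonymous family (first in
    lexicographic order), the codon receiving the usage-bias weight."""
    fam: dict[str, str] = {}
    for codon in sorted(CODONS):
        fam.setdefault(CODON_TO_AA[codon], codon)
    return set(fam.values())


_PREFERRED = _preferred_codons()


def skewed_codon_probs(strength: float, codons: Sequence[str]) -> np.ndarray:
    """Weight 1 + 3*strength for each family's preferred codon, 1 otherwise,
    renormalized; reduces to the uniform distribution at strength 0."""
    w = np.array([1.0 + 3.0 * strength * (c in _PREFERRED) for c in codons])
    return w / w.sum()


def site_probs(enriched: str, strength: float) -> np.ndarray:
    """Nucleotide probabilities (A, C, G, T order) at one context site: an
    extra mass of 0.5*strength is split evenly over the enriched nucleotides
    and taken proportionally from the rest."""
    k = len(enriched)
    p = np.empty(4)
    for i, nt in enumerate(NUCLEOTIDES):
        if nt in enriched:
            p[i] = 0.25 + 0.5 * strength / k
        else:
            p[i] = (1.0 - k * 0.25 - 0.5 * strength) / (4 - k)
    return p


def _draw(rng: np.random.Generator, items: Sequence[str], p=None) -> str:
    return items[rng.choice(len(items), p=p)]


def generate_training_sets(cfg: SynthConfig) -> tuple[Dataset, Dataset]:
    """Positive-like and negative-like OrfRecord datasets under ``cfg``.

    Positives: ATG start, body codons from the skewed distribution, skewed
    stop, Kozak-like upstream context and G-enrichment at site +4 (the first
    base of the second codon, resampled if the override creates a stop).
    Negatives: ATG start, uniform codons, uniform stop and context.
    Reproducible under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    p_body = skewed_codon_probs(cfg.codon_bias_strength, NONSTOP_CODONS)
    p_stop = skewed_codon_probs(cfg.codon_bias_strength, STOPS)
    p_m3 = site_probs("AG", cfg.tis_bias_strength)
    p_m1 = site_probs("C", cfg.tis_bias_strength)
    p_p4 = site_probs("G", cfg.tis_bias_strength)
    uniform = np.full(4, 0.25)
    nts = list(NUCLEOTIDES)

    def make(label: str, index: int) -> OrfRecord:
        positive = label == "positive"
        n_codons = int(rng.integers(lo, hi + 1))
        if positive:
            body = [_draw(rng, NONSTOP_CODONS, p_body) for _ in range(n_codons - 2)]
            stop = _draw(rng, STOPS, p_stop)
            upstream = (_draw(rng, nts, p_m3) + _draw(rng, nts, uniform)
                        + _draw(rng, nts, p_m1))
            if body:  # enrich G at site +4 without creating an in-frame stop
                while True:
                    first = _draw(rng, nts, p_p4) + body[0][1:]
                    if first not in STOP_CODONS:
                        body[0] = first
                        break
        else:
            body = [_draw(rng, NONSTOP_CODONS) for _ in range(n_codons - 2)]
            stop = _draw(rng, STOPS)
            upstream = "".join(_draw(rng, nts) for _ in range(3))
        return OrfRecord(id=f"{label[:3]}_{index:05d}", upstream3=upstream,
                         orf_seq="ATG" + "".join(body) + stop,
                         start_codon="ATG", label=label, source="synth")

    pos = Dataset([make("positive", i) for i in range(cfg.n_pos)])
    neg = Dataset([make("negative", i) for i in range(cfg.n_neg)])
    return pos, neg


# ---------------------------------------------------------------------------
# toy genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedOrf:
    chrom: str
    start: int  # forward-strand, 0-based half-open
    end: int
    strand: str
    start_codon: str
    n_codons: int


def _random_orf(rng: np.random.Generator, start_codon: str, n_codons: int) -> str:
    body = [_draw(rng, NONSTOP_CODONS) for _ in range(n_codons - 2)]
    return start_codon + "".join(body) + _draw(rng, STOPS)


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


def generate_toy_genome(n_contigs: int = 1, contig_len: int = 5000,
                        planted: Sequence[tuple[str, int, str]] = (),
                        seed: int = 42,
                        cds_cover: Sequence[int] = (),
                        decoy_genes: Sequence[tuple[str, int, int, str, str]] = (),
                        ) -> tuple[dict[str, str], list[PlantedOrf], str]:
    """A random genome with ORFs planted at known coordinates.

    ``planted`` lists (start_codon, n_codons, strand) specs, distributed
    round-robin over contigs at evenly spaced offsets.  Planted ORFs contain
    no internal in-frame stop by construction, so a scanner must recover each
    at exactly its planted interval.  ``cds_cover`` selects planted indices to
    wrap in a decoy gene+CDS annotation (same strand, padded 30 nt) so the
    CDS-containment filter can be exercised; ``decoy_genes`` adds extra gene
    features as (chrom, start, end, strand, biotype).

    Returns (contigs, truth, gff3_text).
    """
    rng = np.random.default_rng(seed)
    names = [f"contig{i + 1}" for i in range(n_contigs)]
    contigs = {n: list(rng.choice(list(NUCLEOTIDES), size=contig_len))
               for n in names}
    per_contig: dict[str, list[tuple[str, int, str]]] = {n: [] for n in names}
    for i, spec in enumerate(planted):
        per_contig[names[i % n_contigs]].append(spec)
    truth: list[PlantedOrf] = []
    planted_order: list[PlantedOrf] = []
    for name, specs in per_contig.items():
        if not specs:
            continue
        slot = contig_len // len(specs)
        for j, (start_codon, n_codons, strand) in enumerate(specs):
            span = 3 * n_codons
            if span + 6 > slot:
                raise ValueError(f"planted ORF of {n_codons} codons does not "
                                 f"fit a {slot} nt slot on {name}")
            pos = j * slot + 3  # leave room for genomic upstream context
            orf = _random_orf(rng, start_codon, n_codons)
            insert = orf if strand == "+" else _revcomp(orf)
            contigs[name][pos:pos + span] = list(insert)
            rec = PlantedOrf(name, pos, pos + span, strand, start_codon, n_codons)
            truth.append(rec)
            planted_order.append(rec)
    genome = {n: "".join(s) for n, s in contigs.items()}
    # a planted ORF is exact by construction; but background around it may by
    # chance shadow a DIFFERENT planted ORF — acceptable, truth entries only
    # assert their own span, which is unaffected by background
    gff = ["##gff-version 3"]
    gid = 0
    for idx in cds_cover:
        p = planted_order[idx]
        gid += 1
        s = max(0, p.start - 30)
        e = min(len(genome[p.chrom]), p.end + 30)
        gff.append(f"{p.chrom}\tsynth\tgene\t{s + 1}\t{e}\t.\t{p.strand}\t.\t"
                   f"ID=gene{gid};gene_biotype=protein_coding")
        gff.append(f"{p.chrom}\tsynth\tCDS\t{s + 1}\t{e}\t.\t{p.strand}\t0\t"
                   f"ID=cds{gid};Parent=gene{gid}")
    for chrom, s, e, strand, biotype in decoy_genes:
        gid += 1
        gff.append(f"{chrom}\tsynth\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                   f"ID=gene{gid};gene_biotype={biotype}")
    return genome, truth, "\n".join(gff) + "\n"


def write_genome_files(genome: dict[str, str], truth: Sequence[PlantedOrf],
                       gff3_text: str, out_prefix: str | Path) -> dict[str, Path]:
    """Write genome FASTA, truth BED6 and GFF3 annotation to disk."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": out_prefix.with_suffix(".fa"),
             "bed": out_prefix.with_suffix(".truth.bed"),
             "gff3": out_prefix.with_suffix(".gff3")}
    with open(paths["fasta"], "w") as fa:
        for name, seq in genome.items():
            fa.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fa.write(seq[i:i + 80] + "\n")
    with open(paths["bed"], "w") as bed:
        for p in truth:
            bed.write(f"{p.chrom}\t{p.start}\t{p.end}\t"
                      f"{p.start_codon}_{p.n_codons}\t0\t{p.strand}\n")
    paths["gff3"].write_text(gff3_text)
    return paths
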