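"""Feature encoding for smORF coding-potential classification.

Four feature classes are computed from an ORF plus its 3-nt upstream context:

* basic — ORF length (in codons) and 1-/2-mer composition;
* TIS — per-site log-likelihood ratio of the observed nucleotide at the six
  initiation-context sites (-3, -2, -1 upstream; 4, 5, 6 = the codon after the
  start codon), a Kozak-context signal;
* in-frame — hexamer score (sum of in-frame 6-mer log-likelihood ratios),
  codon usage bias (mean log-ratio of codon-within-amino-acid usage), and the
  Fickett position parameter per nucleotide;
* continuous/discontinuous k-mers — 3-mer, 4-mer and g-gap/g-bigap patterns.

Log-ratios use the natural logarithm.  All count tables are additively
smoothed (pseudocount 1 by default) so every stored probability is positive
and every log-ratio finite.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .seqdata import Dataset, NUCLEOTIDES, OrfRecord

logger = logging.getLogger("smorfkit")

TIS_SITES = (-3, -2, -1, 4, 5, 6)
CODONS = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)]
HEXAMERS = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=6)]
#: codon -> amino-acid class; the three stop codons form one class '*'
CODON_TO_AA = {c: str(Seq(c).translate()) for c in CODONS}

TABLES_FORMAT_VERSION = 1
SCHEMA_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# probability tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTables:
    """Positive/negative probability tables parameterizing the encoders.

    ``site_prob_*[site][x]`` — probability of nucleotide x at TIS site;
    ``codon_usage_*[codon]`` — codon count / encoding-amino-acid count;
    ``hexamer_freq_*[hexamer]`` — relative in-frame hexamer frequency.
    """

    site_prob_pos: dict[int, dict[str, float]]
    site_prob_neg: dict[int, dict[str, float]]
    codon_usage_pos: dict[str, float]
    codon_usage_neg: dict[str, float]
    hexamer_freq_pos: dict[str, float]
    hexamer_freq_neg: dict[str, float]
    pseudocount: float = 1.0

    def swapped(self) -> "FeatureTables":
        """Tables with positive and negative roles exchanged."""
        return FeatureTables(self.site_prob_neg, self.site_prob_pos,
                             self.codon_usage_neg, self.codon_usage_pos,
                             self.hexamer_freq_neg, self.hexamer_freq_pos,
                             self.pseudocount)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format_version": TABLES_FORMAT_VERSION,
            "pseudocount": self.pseudocount,
            "site_prob_pos": {str(k): v for k, v in self.site_prob_pos.items()},
            "site_prob_neg": {str(k): v for k, v in self.site_prob_neg.items()},
            "codon_usage_pos": self.codon_usage_pos,
            "codon_usage_neg": self.codon_usage_neg,
            "hexamer_freq_pos": self.hexamer_freq_pos,
            "hexamer_freq_neg": self.hexamer_freq_neg,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureTables":
        doc = json.loads(Path(path).read_text())
        return cls(
            site_prob_pos={int(k): v for k, v in doc["site_prob_pos"].items()},
            site_prob_neg={int(k): v for k, v in doc["site_prob_neg"].items()},
            codon_usage_pos=doc["codon_usage_pos"],
            codon_usage_neg=doc["codon_usage_neg"],
            hexamer_freq_pos=doc["hexamer_freq_pos"],
            hexamer_freq_neg=doc["hexamer_freq_neg"],
            pseudocount=doc["pseudocount"],
        )


def _site_nucleotide(rec: OrfRecord, site: int) -> str:
    # sites -3..-1 index the upstream context; 4..6 are orf positions 4-6
    # (1-based), i.e. the codon immediately after the start codon
    return rec.upstream3[site + 3] if site < 0 else rec.orf_seq[site - 1]


def in_frame_hexamers(orf_seq: str) -> list[str]:
    """In-frame 6-mers: windows starting at each codon boundary (step 3 nt)."""
    return [orf_seq[i:i + 6] for i in range(0, len(orf_seq) - 5, 3)]


def _fit_site_probs(dataset: Dataset, pseudocount: float) -> dict[int, dict[str, float]]:
    probs: dict[int, dict[str, float]] = {}
    for site in TIS_SITES:
        counts = dict.fromkeys(NUCLEOTIDES, 0)
        for rec in dataset:
            x = _site_nucleotide(rec, site)
            if x in counts:  # N and other ambiguity codes are not counted
                counts[x] += 1
        total = sum(counts.values()) + 4 * pseudocount
        probs[site] = {x: (c + pseudocount) / total for x, c in counts.items()}
    return probs


def _fit_codon_usage(dataset: Dataset, pseudocount: float) -> dict[str, float]:
    counts = dict.fromkeys(CODONS, 0)
    for rec in dataset:
        for codon in rec.codons():
            if codon in counts:
                counts[codon] += 1
    aa_totals: dict[str, float] = {}
    aa_sizes: dict[str, int] = {}
    for codon, aa in CODON_TO_AA.items():
        aa_totals[aa] = aa_totals.get(aa, 0) + counts[codon]
        aa_sizes[aa] = aa_sizes.get(aa, 0) + 1
    usage = {}
    for codon, aa in CODON_TO_AA.items():
        usage[codon] = (counts[codon] + pseudocount) / (
            aa_totals[aa] + aa_sizes[aa] * pseudocount)
    return usage


def _fit_hexamer_freq(dataset: Dataset, pseudocount: float) -> dict[str, float]:
    counts = dict.fromkeys(HEXAMERS, 0)
    total = 0
    for rec in dataset:
        for hexamer in in_frame_hexamers(rec.orf_seq):
            if hexamer in counts:
                counts[hexamer] += 1
                total += 1
    denom = total + len(HEXAMERS) * pseudocount
    return {h: (c + pseudocount) / denom for h, c in counts.items()}


def fit_feature_tables(pos_train: Dataset, neg_train: Dataset,
                       pseudocount: float = 1.0) -> FeatureTables:
    """Fit all probability tables from the two training sets."""
    if len(pos_train) == 0 or len(neg_train) == 0:
        raise ValueError("fit_feature_tables requires non-empty datasets")
    return FeatureTables(
        site_prob_pos=_fit_site_probs(pos_train, pseudocount),
        site_prob_neg=_fit_site_probs(neg_train, pseudocount),
        codon_usage_pos=_fit_codon_usage(pos_train, pseudocount),
        codon_usage_neg=_fit_codon_usage(neg_train, pseudocount),
        hexamer_freq_pos=_fit_hexamer_freq(pos_train, pseudocount),
        hexamer_freq_neg=_fit_hexamer_freq(neg_train, pseudocount),
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

def nucleotide_bias(rec: OrfRecord, tables: FeatureTables) -> np.ndarray:
    """ln(p_pos/p_neg) of the observed nucleotide at each TIS site, ordered
    (-3, -2, -1, 4, 5, 6).  'N' contributes ln(0.25/0.25) = 0."""
    out = np.zeros(len(TIS_SITES))
    for j, site in enumerate(TIS_SITES):
        x = _site_nucleotide(rec, site)
        if x in NUCLEOTIDES:
            out[j] = math.log(tables.site_prob_pos[site][x]
                              / tables.site_prob_neg[site][x])
    return out


def codon_bias(rec: OrfRecord, tables: FeatureTables) -> float:
    """Mean over all codons (stop included) of ln(p_pos(C)/p_neg(C)), where
    p(C) is codon count over encoding-amino-acid count."""
    total, n = 0.0, 0
    for codon in rec.codons():
        n += 1
        if codon in tables.codon_usage_pos:
            total += math.log(tables.codon_usage_pos[codon]
                              / tables.codon_usage_neg[codon])
    return total / n if n else 0.0


def hexamer_score(rec: OrfRecord, tables: FeatureTables) -> float:
    """Sum over in-frame hexamers of ln(freq_pos/freq_neg).

    Deliberately a sum, not a mean: the score grows with ORF length, a signal
    in its own right.  Hexamers containing ambiguity codes contribute 0.
    """
    if len(rec.orf_seq) < 6:
        logger.warning("hexamer_score: ORF shorter than 6 nt, returning 0")
        return 0.0
    total = 0.0
    for hexamer in in_frame_hexamers(rec.orf_seq):
        if hexamer in tables.hexamer_freq_pos:
            total += math.log(tables.hexamer_freq_pos[hexamer]
                              / tables.hexamer_freq_neg[hexamer])
    return total


#: Fickett output order matches the published feature listing
FICKETT_ORDER = "TACG"


def fickett_scores(rec: OrfRecord) -> np.ndarray:
    """Fickett position parameter per nucleotide: with counts (b1, b2, b3) at
    the three codon positions, max/(min + 1).  Order (T, A, C, G)."""
    out = np.zeros(4)
    for j, base in enumerate(FICKETT_ORDER):
        counts = [rec.orf_seq[p::3].count(base) for p in range(3)]
        out[j] = max(counts) / (min(counts) + 1)
    return out


def kmer_freq(rec: OrfRecord, k: int) -> np.ndarray:
    """Sliding-window (step 1) k-mer relative frequencies over the ORF,
    lexicographic order; windows containing non-ACGT letters are skipped."""
    if k not in (1, 2, 3, 4):
        raise ValueError("k must be in {1, 2, 3, 4}")
    index = {"".join(p): i for i, p in
             enumerate(itertools.product(NUCLEOTIDES, repeat=k))}
    out = np.zeros(4 ** k)
    seq = rec.orf_seq
    for i in range(len(seq) - k + 1):
        j = index.get(seq[i:i + k])
        if j is not None:
            out[j] += 1
    total = out.sum()
    return out / total if total else out


def gap_freq(rec: OrfRecord, g: int, mode: str = "gap") -> np.ndarray:
    """Discontinuous k-mer frequencies.

    mode='gap': nucleotide pairs x .{g} y (16 patterns);
    mode='bigap': dinucleotide pairs x1x2 .{g} y1y2 (256 patterns).
    Sliding step 1, normalized to sum 1; all-zero when the ORF is shorter than
    the pattern span.
    """
    if g not in (1, 2, 3):
        raise ValueError("g must be in {1, 2, 3}")
    if mode not in ("gap", "bigap"):
        raise ValueError("mode must be 'gap' or 'bigap'")
    w = 1 if mode == "gap" else 2
    index = {"".join(p): i for i, p in
             enumerate(itertools.product(NUCLEOTIDES, repeat=2 * w))}
    out = np.zeros(len(index))
    seq = rec.orf_seq
    span = 2 * w + g
    for i in range(len(seq) - span + 1):
        key = seq[i:i + w] + seq[i + w + g:i + span]
        j = index.get(key)
        if j is not None:
            out[j] += 1
    total = out.sum()
    return out / total if total else out


# ---------------------------------------------------------------------------
# schemas
# ---------------------------------------------------------------------------

#: component name -> (dimension, needs_tables)
COMPONENTS: dict[str, tuple[int, bool]] = {
    "orf_length": (1, False),
    "1-mer": (4, False),
    "2-mer": (16, False),
    "nucleotide_bias": (6, True),
    "hexamer_score": (1, True),
    "codon_bias": (1, True),
    "fickett": (4, False),
    "3-mer": (64, False),
    "4-mer": (256, False),
    "1-gap": (16, False),
    "2-gap": (16, False),
    "3-gap": (16, False),
    "1-bigap": (256, False),
    "2-bigap": (256, False),
    "3-bigap": (256, False),
}

COMPLETE_ORDER = list(COMPONENTS)
REDUCED33_ORDER = COMPLETE_ORDER[:7]

#: the published relevance/redundancy ranking of the 33 retained features;
#: the final model drops the last-ranked one (2-mer TT)
RANKED33 = [
    "ORF length", "Nucleotide bias: -3", "Fickett: T", "Fickett: A",
    "Fickett: C", "Fickett: G", "2-mer: CG", "2-mer: GA", "2-mer: CC",
    "2-mer: TA", "2-mer: CT", "2-mer: AT", "2-mer: GC", "2-mer: GG",
    "2-mer: GT", "2-mer: TC", "2-mer: TG", "2-mer: CA", "1-mer: T",
    "2-mer: AG", "Nucleotide bias: 4", "Nucleotide bias: 5", "Hexamer score",
    "Codon bias", "Nucleotide bias: -2", "Nucleotide bias: -1", "2-mer: AC",
    "2-mer: AA", "Nucleotide bias: 6", "1-mer: A", "1-mer: C", "1-mer: G",
    "2-mer: TT",
]


def component_feature_names(component: str) -> list[str]:
    """Human-readable name of every scalar within a component."""
    if component == "orf_length":
        return ["ORF length"]
    if component == "nucleotide_bias":
        return [f"Nucleotide bias: {s}" for s in TIS_SITES]
    if component == "hexamer_score":
        return ["Hexamer score"]
    if component == "codon_bias":
        return ["Codon bias"]
    if component == "fickett":
        return [f"Fickett: {b}" for b in FICKETT_ORDER]
    if component.endswith("-mer"):
        k = int(component[0])
        return [f"{k}-mer: " + "".join(p)
                for p in itertools.product(NUCLEOTIDES, repeat=k)]
    if component.endswith("gap"):
        g = int(component[0])
        w = 2 if "bigap" in component else 1
        return [f"{component}: " + "".join(p[:w]) + "_" * g + "".join(p[w:])
                for p in itertools.product(NUCLEOTIDES, repeat=2 * w)]
    raise KeyError(f"unknown component {component!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered layout of a feature vector.

    ``components`` lists (component_name, dimension) pairs; when ``select`` is
    set the vector is instead the named scalar features, in that order, drawn
    from the listed components.
    """

    name: str
    components: tuple[tuple[str, int], ...]
    select: tuple[str, ...] = ()

    @property
    def dimension(self) -> int:
        if self.select:
            return len(self.select)
        return sum(d for _, d in self.components)

    def feature_names(self) -> list[str]:
        if self.select:
            return list(self.select)
        return [n for comp, _ in self.components
                for n in component_feature_names(comp)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "format_version": SCHEMA_FORMAT_VERSION,
            "name": self.name,
            "components": list(self.components),
            "select": list(self.select),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        doc = json.loads(Path(path).read_text())
        return cls(doc["name"], tuple((c, d) for c, d in doc["components"]),
                   tuple(doc["select"]))


def _schema(name: str, order: list[str], select: tuple[str, ...] = ()) -> FeatureSchema:
    return FeatureSchema(name, tuple((c, COMPONENTS[c][0]) for c in order), select)


SCHEMAS: dict[str, FeatureSchema] = {
    "complete": _schema("complete", COMPLETE_ORDER),
    "reduced33": _schema("reduced33", REDUCED33_ORDER),
    "final32": _schema("final32", REDUCED33_ORDER, tuple(RANKED33[:32])),
}


def get_schema(name: str) -> FeatureSchema:
    try:
        return SCHEMAS[name]
    except KeyError:
        raise KeyError(f"unknown schema {name!r}; known: {sorted(SCHEMAS)}") from None


def _component_vector(rec: OrfRecord, tables: FeatureTables | None,
                      component: str) -> np.ndarray:
    if component not in COMPONENTS:
        raise KeyError(f"unknown component {component!r}")
    if component == "orf_length":
        return np.array([float(rec.n_codons)])
    if component == "nucleotide_bias":
        return nucleotide_bias(rec, tables)
    if component == "hexamer_score":
        return np.array([hexamer_score(rec, tables)])
    if component == "codon_bias":
        return np.array([codon_bias(rec, tables)])
    if component == "fickett":
        return fickett_scores(rec)
    if component.endswith("-mer"):
        return kmer_freq(rec, int(component[0]))
    if component.endswith("bigap"):
        return gap_freq(rec, int(component[0]), "bigap")
    if component.endswith("gap"):
        return gap_freq(rec, int(component[0]), "gap")
    raise KeyError(f"unknown component {component!r}")


def encode(rec: OrfRecord, tables: FeatureTables | None,
           schema: FeatureSchema) -> np.ndarray:
    """Encode one record under a schema.  Pure and deterministic."""
    needs_tables = any(COMPONENTS.get(c, (0, True))[1] for c, _ in schema.components)
    if needs_tables and tables is None:
        raise ValueError(f"schema {schema.name!r} requires fitted FeatureTables")
    parts = {c: _component_vector(rec, tables, c) for c, _ in schema.components}
    if schema.select:
        values = {}
        for comp, _ in schema.components:
            for fname, v in zip(component_feature_names(comp), parts[comp]):
                values[fname] = v
        try:
            return np.array([values[n] for n in schema.select])
        except KeyError as exc:
            raise KeyError(f"schema selects unknown feature {exc}") from None
    return np.concatenate([parts[c] for c, _ in schema.components])


def encode_dataset(dataset: Dataset, tables: FeatureTables | None,
                   schema: FeatureSchema) -> np.ndarray:
    """Feature matrix (rows follow dataset order)."""
    if len(dataset) == 0:
        return np.zeros((0, schema.dimension))
    return np.vstack([encode(r, tables, schema) for r in dataset])
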