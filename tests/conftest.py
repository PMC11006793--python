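import numpy as np
import pytest

from smorfkit.features import fit_feature_tables, get_schema
from smorfkit.seqdata import Dataset, OrfRecord
from smorfkit.synth import SynthConfig, generate_training_sets


def make_record(orf_seq, upstream3="CCA", rec_id="r1", label="unknown"):
    return OrfRecord(id=rec_id, upstream3=upstream3, orf_seq=orf_seq,
                     start_codon=orf_seq[:3], label=label)


@pytest.fixture(scope="session")
def small_sets():
    """Small biased positive/negative training sets (shared, read-only)."""
    cfg = SynthConfig(n_pos=80, n_neg=80, codon_bias_strength=1.0,
                      tis_bias_strength=1.0, seed=7)
    return generate_training_sets(cfg)


@pytest.fixture(scope="session")
def small_tables(small_sets):
    pos, neg = small_sets
    return fit_feature_tables(pos, neg)


@pytest.fixture(scope="session")
def uniform_tables():
    """Tables fitted on identical pos/neg data: every log-ratio is zero."""
    recs = Dataset([make_record("ATGAAACCCGGGTTTTAA", rec_id=f"u{i}")
                    for i in range(4)])
    return fit_feature_tables(recs, Dataset(list(recs.records)))


@pytest.fixture(scope="session")
def reduced33():
    return get_schema("reduced33")


def random_orf_record(rng, n_codons=None, rec_id="r"):
    """A random valid OrfRecord (uniform non-stop codons, uniform stop)."""
    from smorfkit.features import CODONS
    from smorfkit.seqdata import STOP_CODONS
    nonstop = [c for c in CODONS if c not in STOP_CODONS]
    if n_codons is None:
        n_codons = int(rng.integers(2, 40))
    body = [nonstop[rng.integers(len(nonstop))] for _ in range(n_codons - 2)]
    stop = sorted(STOP_CODONS)[rng.integers(3)]
    start = nonstop[rng.integers(len(nonstop))]
    seq = start + "".join(body) + stop
    upstream = "".join("ACGT"[rng.integers(4)] for _ in range(3))
    return make_record(seq, upstream3=upstream, rec_id=rec_id)
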