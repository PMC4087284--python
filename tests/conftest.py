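import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ranksig",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ranksig")


def es_walk(ranking, gene_set):
    """Independent explicit running-sum oracle for the enrichment score.

    Walks the ranked list position by position: +1/m on a hit, -1/(G-m) on
    a miss; returns the excursion of maximum absolute magnitude (positive
    value on an exact magnitude tie). Exact rational arithmetic so the
    tie-break is decided correctly.
    """
    from fractions import Fraction

    gene_set = set(gene_set)
    G, m = len(ranking), len(gene_set)
    run, values = Fraction(0), []
    for g in ranking:
        run += Fraction(1, m) if g in gene_set else -Fraction(1, G - m)
        values.append(run)
    hi, lo = max(values), min(values)
    return float(hi if hi >= -lo else lo)


def directional_es_walk(top, bottom, ranking):
    """Oracle for a two-part signature score: top on the descending list,
    bottom on the reversed list, averaged."""
    return (es_walk(ranking, top) + es_walk(list(ranking)[::-1], bottom)) / 2.0


@pytest.fixture
def rng():
    return np.random.default_rng(20140618)


@pytest.fixture
def small_cohort(rng):
    """30 probes x 8 samples of positive intensities, no group structure."""
    probes = [f"g{i:02d}" for i in range(30)]
    samples = [f"s{i}" for i in range(8)]
    values = rng.lognormal(5.0, 1.0, size=(30, 8))
    return pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                        columns=pd.Index(samples, name="sample_id"))


def write_tsv(path, text):
    path.write_text(text)
    return path
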