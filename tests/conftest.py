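import numpy as np
import pandas as pd
import pytest

from prsport.io_formats import GenotypeMatrix


def make_panel(records, n_samples=None, dosage=None, missing=None):
    """Build a small GenotypeMatrix from (chrom, pos, rsid, ref, alt, info, af) tuples.

    When ``dosage`` is omitted, deterministic dosages matching each variant's
    allele frequency are synthesised.
    """
    meta = pd.DataFrame(records, columns=["chromosome", "position", "rsid",
                                          "ref_allele", "alt_allele", "info_score",
                                          "alt_frequency"])
    m = len(meta)
    if dosage is None:
        n = n_samples or 8
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, meta["alt_frequency"].to_numpy()[None, :],
                              size=(n, m)).astype(float)
    n = dosage.shape[0]
    if missing is None:
        missing = np.zeros_like(dosage, dtype=bool)
    g = GenotypeMatrix(sample_ids=[f"S{i}" for i in range(n)], variant_meta=meta,
                       dosage=dosage, missing=missing)
    g.variant_meta["call_rate"] = 1.0
    return g


@pytest.fixture
def tiny_panel():
    """Three-variant panel used across harmonization/scoring tests."""
    return make_panel([
        ("1", 100, "rs1", "G", "A", 0.95, 0.30),
        ("1", 200, "rs2", "T", "G", 0.90, 0.20),
        ("2", 300, "rs3", "A", "T", 0.99, 0.45),
    ], n_samples=6)
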