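import numpy as np
import pandas as pd
import pytest

from astrocilia import synthetic
from astrocilia.motifs import PWM

CONSENSUS = "GTTGCCATGGCAAC"  # RFX-like palindromic consensus


def consensus_counts(consensus, weight=100):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.ones((len(consensus), 4))
    for i, base in enumerate(consensus.upper()):
        counts[i, idx[base]] = weight
    return counts


@pytest.fixture(scope="session")
def small_genome():
    return synthetic.make_genome(50, n_chroms=1, chrom_len=1_000_000, seed=1)


@pytest.fixture(scope="session")
def signal_config():
    return synthetic.PlantedSignalConfig(seed=2)


@pytest.fixture(scope="session")
def strong_pwm():
    """Near-deterministic PWM whose only above-threshold hit is the consensus."""
    return PWM.from_counts("consensus", consensus_counts(CONSENSUS))


@pytest.fixture(scope="session")
def soft_pwm():
    """Permissive PWM (weight-6 counts) producing abundant background hits."""
    return PWM.from_counts("soft", consensus_counts("TTGCCATGG", weight=6))


def toy_table(rows):
    """Differential table from (feature_id, log2fc, pvalue, qvalue) tuples."""
    return pd.DataFrame(rows, columns=["feature_id", "log2fc", "pvalue",
                                       "qvalue"])
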