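import numpy as np
import pytest

from restore import FeatureTable, PairConfig, SimConfig, lemma1_fixture


@pytest.fixture
def small_table():
    """Two samples, three markers, hand-written values."""
    return FeatureTable(
        cell_id=np.array(["c1", "c2", "c3", "c1", "c2"], dtype=object),
        sample_id=np.array(["s1", "s1", "s1", "s2", "s2"], dtype=object),
        markers=["CK7", "CD45", "CD8"],
        intensities=np.array(
            [
                [10.0, 1.0, 1.5],
                [9.0, 1.2, 0.8],
                [1.0, 8.0, 7.0],
                [5.0, 0.5, 0.6],
                [0.5, 4.0, 3.5],
            ]
        ),
    )


@pytest.fixture
def random_table():
    """Seeded random 40-cell, 4-marker table across two samples."""
    rng = np.random.default_rng(42)
    n = 40
    return FeatureTable(
        cell_id=np.array([f"c{i}" for i in range(n)], dtype=object),
        sample_id=np.array(["a"] * 20 + ["b"] * 20, dtype=object),
        markers=["m1", "m2", "m3", "m4"],
        intensities=rng.gamma(2.0, 1.5, size=(n, 4)),
    )


@pytest.fixture
def pair_config():
    return PairConfig({"CK7": ["CD45", "CD8"], "CD45": ["CK7"]})


@pytest.fixture
def lemma_pair():
    """Well-separated three-group fixture (SBR 10)."""
    cfg = SimConfig(sbr=10.0, group_sizes=(60, 60, 60), seed=5)
    return lemma1_fixture(cfg)


def valid_split_ari(labels, truth):
    """ARI of a binary split against whichever of the two admissible
    splits it matches best.

    A mutually exclusive pair slice may legitimately split as
    [reference-positive | rest] or [reference-positive + double-negative
    | target-positive]; both isolate a clean negative-control group for
    the reference marker.
    """
    from sklearn.metrics import adjusted_rand_score

    return max(
        adjusted_rand_score((truth.group == 1).astype(int), labels),
        adjusted_rand_score((truth.group != 2).astype(int), labels),
    )
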