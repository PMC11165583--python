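import numpy as np
import pandas as pd
import pytest

import plasmatrace as pt


@pytest.fixture(scope="session")
def reference_table():
    return pt.load_reference_table()


@pytest.fixture(scope="session")
def p2_noisefree_matrix():
    """Noise-free p2 cohort converted to mg/dL under identity calibration."""
    table, truth = pt.generate_quant_table("p2_apr", noise_cv=0.0, seed=0)
    model = pt.fit_concentration_model(table, pt.load_reference_table())
    return pt.lfq_to_concentration(model, table), truth


@pytest.fixture(scope="session")
def p2_sec_run():
    """Noise-free SEC run at the p2 APR peak with its truth record."""
    table, truth = pt.generate_sec_run("p2_apr", timepoint=2, noise_cv=0.0, seed=0)
    return table, truth


@pytest.fixture(scope="session")
def p2_mw_calibration(p2_sec_run):
    table, _ = p2_sec_run
    return pt.fit_mw_calibration(table.calibrants)


def brute_force_complete_linkage(dist: pd.DataFrame) -> dict[frozenset, float]:
    """O(n^3) agglomeration oracle: complete linkage, lexicographic ties.

    Returns the cophenetic distance for every leaf pair as a dict keyed by
    frozenset({a, b}).
    """
    labels = sorted(dist.index)
    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    coph: dict[frozenset, float] = {}
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    dist.loc[a, b] for a in clusters[i] for b in clusters[j]
                )
                key = (d, clusters[i][0], clusters[j][0])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[frozenset((a, b))] = d
        merged = tuple(sorted(clusters[i] + clusters[j]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return coph


@pytest.fixture
def make_random_distances():
    def _make(n: int, seed: int) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.05, 2.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"P{i}" for i in range(n)]
        return pd.DataFrame(m, index=labels, columns=labels)

    return _make
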