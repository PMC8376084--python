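import numpy as np
import pandas as pd
import pytest

from igcoat.feature_table import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_table():
    """3 features x 4 samples with hand-picked sums for boundary tests."""
    counts = np.array(
        [
            [100, 200, 3000, 0],
            [200, 150, 3000, 1],
            [100, 150, 3000, 0],
        ]
    )
    return FeatureTable(counts, ["f1", "f2", "f3"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def toy_metadata():
    rows = []
    for i, (dog, rep, run, ctrl) in enumerate(
        [
            ("d1", 1, "run1", False),
            ("d1", 2, "run2", False),
            ("d2", 1, "run1", False),
            ("c1", 1, "run1", True),
        ],
        start=1,
    ):
        rows.append(
            {
                "sample_id": f"s{i}",
                "dog_id": dog,
                "cohort": "control" if ctrl else "healthy",
                "stage": "control" if ctrl else "before",
                "ig_class": "control" if ctrl else "IgA",
                "fraction": "control" if ctrl else "presort",
                "run": run,
                "replicate": rep,
                "is_control": ctrl,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def factor_metadata():
    """Full 2 x 4 x 2 crossing of ig_class x cohort x stage over 8 dogs."""
    rows = []
    dogs = [
        ("d1", "healthy"), ("d2", "healthy"),
        ("d3", "DRE"), ("d4", "DRE"),
        ("d5", "ARE"), ("d6", "ARE"),
        ("d7", "IRE"), ("d8", "IRE"),
    ]
    for dog, cohort in dogs:
        for stage in ("before", "after"):
            for ig in ("IgA", "IgG"):
                rows.append(
                    {
                        "dog_id": dog,
                        "cohort": cohort,
                        "stage": stage,
                        "ig_class": ig,
                    }
                )
    return pd.DataFrame(rows)
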