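"""Shared fixtures: small synthetic cohorts with known latent structure."""

import numpy as np
import pandas as pd
import pytest

from lctraj.lclmm import LCLMMParams, LCLMMSpec, build_design
from lctraj.simulate import SyntheticConfig, generate_cohort, generate_outcome_tracks


@pytest.fixture(scope="session")
def small_cohort():
    """645 incident subjects, three latent classes, no reference group."""
    cfg = SyntheticConfig(seed=7, n_diabetes_free=0)
    dataset, truth = generate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def single_class_cohort():
    """80 subjects from one trajectory class (ordinary LMM data)."""
    cfg = SyntheticConfig(
        seed=4,
        n_subjects=80,
        n_diabetes_free=0,
        class_proportions=(1.0,),
        class_coef=((28.0, 0.1, 0.0, 0.0),),
    )
    dataset, truth = generate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def tiny_design(single_class_cohort):
    """5-subject design for direct-density likelihood checks."""
    _, dataset, _ = single_class_cohort
    keep = dataset.subjects.index[:5]
    recs = dataset.records[dataset.records["subject_id"].isin(keep)]
    spec = LCLMMSpec(n_classes=1)
    return build_design(recs, spec), spec


@pytest.fixture(scope="session")
def tiny_params(tiny_design):
    design, _ = tiny_design
    return LCLMMParams(
        pi=np.ones(1),
        delta=np.array([[27.0, 0.1, 0.01, 0.0]]),
        beta=0.02 + 0.1 * np.arange(design.q),
        B=np.array([[9.0, 0.1], [0.1, 0.04]]),
        sigma2=0.64,
    )


@pytest.fixture(scope="session")
def tracked_cohort():
    """Moderate cohort with risk-factor tracks and a diabetes-free group."""
    cfg = SyntheticConfig(seed=5, n_subjects=645, n_diabetes_free=1000)
    dataset, truth = generate_cohort(cfg)
    dataset = generate_outcome_tracks(cfg, dataset, truth)
    labels = truth.set_index("subject_id")["true_class"].map(
        lambda g: "diabetes-free" if g == 0 else f"class_{g}"
    )
    return cfg, dataset, truth, labels


def two_group_null_frame(rng: np.random.Generator, n_per: int = 150):
    """Two groups generated from the identical linear mixed model."""
    m = 4
    frames = []
    for label in ("class_1", "class_2"):
        b0 = rng.normal(0, 2.0, n_per)
        b1 = rng.normal(0, 0.1, n_per)
        age = rng.normal(60, 7, n_per)
        sex = (rng.random(n_per) < 0.7).astype(int)
        t = np.minimum(
            -5.0 * np.arange(m - 1, -1, -1)[None, :] + rng.uniform(-1, 1, (n_per, m)),
            0.0,
        )
        y = (
            27.0
            + 0.1 * t
            + b0[:, None]
            + b1[:, None] * t
            + 0.02 * (age[:, None] - 60)
            - 0.5 * sex[:, None]
            + rng.normal(0, 0.8, (n_per, m))
        )
        sid = np.char.add(f"{label}_s", np.arange(n_per).astype(str))
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(sid, m),
                    "group_truth": label,
                    "t": t.ravel(),
                    "y": y.ravel(),
                    "age": (age[:, None] + t).ravel(),
                    "sex": np.repeat(sex, m),
                    "phase": np.tile([3, 5, 7, 9], n_per),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
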