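import pandas as pd
import pytest

from lnccompartment import SimulationConfig, generate_dataset


def small_profile(**overrides):
    base = dict(
        n_lnc=2000,
        n_coding=1500,
        de_counts={
            "heart": {"up": 100, "down": 150},
            "plasma": {"up": 200, "down": 180},
            "whole_blood": {"up": 120, "down": 160},
        },
    )
    base.update(overrides)
    return SimulationConfig.paper_profile(**base)


def tiny_profile(n_lnc, n_coding, **overrides):
    """Reduced profile with DE counts scaled to the probe count."""
    counts = {
        k: {"up": max(1, int(0.03 * n_lnc)), "down": max(1, int(0.05 * n_lnc))}
        for k in ("heart", "plasma", "whole_blood")
    }
    return small_profile(n_lnc=n_lnc, n_coding=n_coding, de_counts=counts, **overrides)


@pytest.fixture(scope="session")
def small_cfg():
    return small_profile()


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_dataset(small_cfg, 7)


@pytest.fixture(scope="session")
def paper_cfg():
    return SimulationConfig.paper_profile()


@pytest.fixture(scope="session")
def paper_study(paper_cfg):
    """The full planted study at the profile's default seed (42)."""
    return generate_dataset(paper_cfg, 42)


@pytest.fixture(scope="session")
def small_de(small_study):
    from lnccompartment import expression_core as ec

    return {
        "lnc": {
            c: ec.call_de(small_study.lnc_expr, small_study.lnc_expr.pair(c))
            for c in ec.COMPARTMENTS
        },
        "mrna": {
            c: ec.call_de(small_study.mrna_expr, small_study.mrna_expr.pair(c))
            for c in ec.COMPARTMENTS
        },
    }


def make_expression(intensity: pd.DataFrame, flags: pd.DataFrame | None = None, samples=None):
    """Hand-built ExpressionMatrix helper for unit tests."""
    from lnccompartment.expression_core import ExpressionMatrix

    if flags is None:
        flags = pd.DataFrame("P", index=intensity.index, columns=intensity.columns)
    if samples is None:
        samples = pd.DataFrame(
            {"compartment": None, "condition": None}, index=intensity.columns
        )
    tr = pd.Series(list(intensity.index), index=intensity.index, name="transcript_id")
    return ExpressionMatrix(intensity, flags, tr, samples)
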