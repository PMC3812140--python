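"""Expression-matrix handling: I/O, quantile normalization, flag filtering,
and fold-change differential-expression calling.

The study design is the pooled two-array-per-compartment microarray layout:
for each compartment (heart, whole blood, plasma) there is exactly one heart-
failure (HF) array and one control array, each hybridized with pooled RNA.
With no replicates, differential expression is a pure fold-change filter
between the paired arrays — upregulated if HF/control >= 2.0, downregulated
if <= 0.5 (both inclusive) — restricted to probes whose detection flags are
Present or Marginal on both arrays of the pair ("2 out of 2").
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("heart", "whole_blood", "plasma")
CONDITIONS = ("HF", "control")
FLAGS = ("P", "M", "A")


class ExpressionError(ValueError):
    """Raised for malformed expression tables or invalid sample references."""


@dataclass
class ExpressionMatrix:
    """Probe × sample intensity table with Present/Marginal/Absent flags.

    Attributes
    ----------
    intensity :
        DataFrame (probes × samples), non-negative.
    flags :
        DataFrame of the same shape with values in {'P','M','A'}.
    probe_transcript :
        Series mapping probe id -> transcript id.
    samples :
        DataFrame indexed by sample id with columns ``compartment`` and
        ``condition``.
    """

    intensity: pd.DataFrame
    flags: pd.DataFrame
    probe_transcript: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.intensity.shape != self.flags.shape:
            raise ExpressionError("intensity and flags shapes differ")
        if not self.intensity.index.equals(self.flags.index) or not self.intensity.columns.equals(
            self.flags.columns
        ):
            raise ExpressionError("intensity and flags must share index and columns")
        if self.intensity.index.has_duplicates:
            dups = self.intensity.index[self.intensity.index.duplicated()][:5]
            raise ExpressionError(f"duplicate probe ids: {list(dups)}")
        if self.intensity.isna().any().any():
            raise ExpressionError("missing intensity cells")
        if (self.intensity.values < 0).any():
            raise ExpressionError("negative intensities")
        bad = ~self.flags.isin(FLAGS)
        if bad.any().any():
            raise ExpressionError("flags must be P, M or A")
        missing = set(self.intensity.columns) - set(self.samples.index)
        if missing:
            raise ExpressionError(f"samples without metadata: {sorted(missing)}")

    @property
    def probes(self) -> pd.Index:
        return self.intensity.index

    def sample_id(self, compartment: str, condition: str) -> str:
        sel = self.samples[
            (self.samples["compartment"] == compartment)
            & (self.samples["condition"] == condition)
        ]
        if len(sel) != 1:
            raise ExpressionError(
                f"expected exactly one ({compartment}, {condition}) sample, found {len(sel)}"
            )
        return sel.index[0]

    def pair(self, compartment: str) -> tuple[str, str]:
        """(HF sample id, control sample id) for a compartment."""
        return self.sample_id(compartment, "HF"), self.sample_id(compartment, "control")


def _samples_from_names(names: Sequence[str]) -> pd.DataFrame:
    """Infer (compartment, condition) metadata from '<compartment>_<condition>' ids."""
    rows = {}
    for name in names:
        comp, _, cond = name.rpartition("_")
        if comp not in COMPARTMENTS or cond not in CONDITIONS:
            comp, cond = None, None
        rows[name] = {"compartment": comp, "condition": cond}
    return pd.DataFrame.from_dict(rows, orient="index")


def read_expression_table(
    path: str | os.PathLike, samples: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Read the tab-separated expression dialect.

    Columns: ``probe_id``, ``transcript_id``, then for each sample ``<s>``
    (intensity) and ``<s>_flag``.  Sample metadata defaults to parsing
    ``<compartment>_<condition>`` sample names.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "transcript_id"):
        if col not in df.columns:
            raise ExpressionError(f"{path}: missing required column {col!r}")
    sample_names = [c for c in df.columns if c not in ("probe_id", "transcript_id") and not c.endswith("_flag")]
    for s in sample_names:
        if f"{s}_flag" not in df.columns:
            raise ExpressionError(f"{path}: missing flag column {s}_flag")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        line = int(df.index[df["probe_id"] == dup][1]) + 2
        raise ExpressionError(f"{path}: duplicate probe id {dup!r} at line {line}")
    intensity = pd.DataFrame(index=pd.Index(df["probe_id"], name="probe_id"))
    for s in sample_names:
        vals = pd.to_numeric(df[s], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2
            raise ExpressionError(f"{path}: non-numeric intensity in column {s!r} at line {line}")
        if (vals < 0).any():
            line = int(vals.index[vals < 0][0]) + 2
            raise ExpressionError(f"{path}: negative intensity in column {s!r} at line {line}")
        intensity[s] = vals.values
    flags = pd.DataFrame(index=intensity.index)
    for s in sample_names:
        fl = df[f"{s}_flag"]
        bad = ~fl.isin(FLAGS)
        if bad.any():
            line = int(fl.index[bad][0]) + 2
            raise ExpressionError(f"{path}: invalid flag in column {s}_flag at line {line}")
        flags[s] = fl.values
    probe_transcript = pd.Series(df["transcript_id"].values, index=intensity.index, name="transcript_id")
    if samples is None:
        samples = _samples_from_names(sample_names)
    return ExpressionMatrix(intensity, flags, probe_transcript, samples)


def write_expression_table(m: ExpressionMatrix, path: str | os.PathLike) -> None:
    out = pd.DataFrame({"probe_id": m.probes, "transcript_id": m.probe_transcript.values})
    for s in m.intensity.columns:
        out[s] = m.intensity[s].values
        out[f"{s}_flag"] = m.flags[s].values
    out.to_csv(path, sep="\t", index=False)


def quantile_normalize(m: ExpressionMatrix, per_compartment: bool = False) -> ExpressionMatrix:
    """Force all sample columns to share one intensity distribution.

    Every column's sorted values are replaced by the per-rank mean of all
    columns' order statistics; ties within a column receive the mean of the
    tied ranks' target values.  With ``per_compartment`` the procedure is run
    separately on each compartment's pair of arrays.
    """
    if m.intensity.shape[0] == 0 or m.intensity.shape[1] == 0:
        raise ExpressionError("cannot quantile-normalize an empty matrix")
    if per_compartment:
        parts = []
        for comp in dict.fromkeys(m.samples["compartment"].dropna()):
            cols = m.samples.index[m.samples["compartment"] == comp]
            parts.append(_qn_frame(m.intensity[list(cols)]))
        normalized = pd.concat(parts, axis=1)[m.intensity.columns]
    else:
        normalized = _qn_frame(m.intensity)
    return ExpressionMatrix(normalized, m.flags.copy(), m.probe_transcript.copy(), m.samples.copy())


def _qn_frame(df: pd.DataFrame) -> pd.DataFrame:
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    ranks_grid = np.arange(1, n + 1, dtype=float)
    from scipy.stats import rankdata

    for j in range(x.shape[1]):
        r = rankdata(x[:, j], method="average")
        # fractional (tied) ranks interpolate between adjacent target values,
        # which equals the mean of the tied ranks' targets for .5 ranks
        out[:, j] = np.interp(r, ranks_grid, target)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def flag_filter(m: ExpressionMatrix, pair: tuple[str, str]) -> pd.Index:
    """Probes with Present/Marginal flags on both arrays of the pair."""
    for s in pair:
        if s not in m.flags.columns:
            raise ExpressionError(f"unknown sample id {s!r}")
    ok = m.flags[pair[0]].isin(("P", "M")) & m.flags[pair[1]].isin(("P", "M"))
    return m.probes[ok.values]


def call_de(
    m: ExpressionMatrix,
    pair: tuple[str, str],
    up: float = 2.0,
    down: float = 0.5,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Fold-change DE calls for one (HF, control) array pair.

    fc = max(HF, floor) / max(control, floor); direction 'up' iff fc >= up,
    'down' iff fc <= down (both inclusive), else 'unchanged'.  Probes failing
    the flag filter are 'unchanged' with ``passed_flag_filter`` False.
    Returns a DataFrame indexed by probe id with columns fc, log2fc,
    direction, passed_flag_filter.
    """
    if not (up > 1 > down > 0):
        raise ExpressionError(f"need up > 1 > down > 0, got up={up}, down={down}")
    if floor <= 0:
        raise ExpressionError("floor must be positive")
    hf_id, ctrl_id = pair
    for s in pair:
        if s not in m.intensity.columns:
            raise ExpressionError(f"unknown sample id {s!r}")
    hf = np.maximum(m.intensity[hf_id].to_numpy(dtype=float), floor)
    ctrl = np.maximum(m.intensity[ctrl_id].to_numpy(dtype=float), floor)
    fc = hf / ctrl
    passed = m.probes.isin(flag_filter(m, pair))
    direction = np.where(fc >= up, "up", np.where(fc <= down, "down", "unchanged"))
    direction = np.where(passed, direction, "unchanged")
    return pd.DataFrame(
        {
            "fc": fc,
            "log2fc": np.log2(fc),
            "direction": direction,
            "passed_flag_filter": passed,
        },
        index=m.probes,
    )


def de_counts(de: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) of a DE table."""
    return int((de["direction"] == "up").sum()), int((de["direction"] == "down").sum())


def write_de_table(de: pd.DataFrame, compartment: str, path: str | os.PathLike) -> None:
    out = de.copy()
    out.insert(0, "compartment", compartment)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
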