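"""Evaluation metrics for set surgical occlusions and method agreement.

Covers four layers of analysis:

* **maxillary movement** — per-axis displacement of the upper incisal point
  and the right/left first-molar mesio-buccal cusp tips under a planned
  rigid transform, in patient-frame signs (right −/left +, down −/up +,
  back −/forward +);
* **inter-jaw relationship** — midline deviation (x), overbite (y) and
  overjet (z) from the incisal point pair, plus component-wise molar
  relationships; signs chosen so a normal Class I occlusion has positive
  overbite and overjet, and a desirable range of 0–3.5 mm is flagged
  following the index of orthodontic treatment need;
* **gold-standard tolerance interval** — absolute mean inter-observer
  difference ± 1 SD (floored at 0) with the fraction of test values covered
  (≥ 68 % expected when spreads match under normality);
* **agreement statistics** — ICC(2,1) (two-way random effects, absolute
  agreement, single measurement) with the 0.75–0.90 good / > 0.90 very good
  qualitative bands, and Bland–Altman mean difference with ± 1.96 SD limits
  of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh_core import LandmarkSet, RigidTransform

__all__ = [
    "MovementDelta",
    "JawRelationship",
    "ToleranceInterval",
    "ICCResult",
    "BlandAltmanResult",
    "DESIRABLE_RANGE_MM",
    "maxillary_movement",
    "jaw_relationship",
    "tolerance_interval",
    "icc_absolute_agreement",
    "icc_from_table",
    "bland_altman",
]

MOVEMENT_LANDMARKS = ("UI", "UMcusp_r", "UMcusp_l")
DESIRABLE_RANGE_MM = (0.0, 3.5)  # desirable overbite/overjet window
LOA_FACTOR = 1.96  # Bland–Altman limits of agreement


@dataclass
class MovementDelta:
    """Per-landmark (dx, dy, dz) displacement in mm, patient-frame signs."""

    deltas: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.deltas[name]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"landmark": k, "dx": v[0], "dy": v[1], "dz": v[2]}
                for k, v in self.deltas.items()
            ]
        )


@dataclass
class JawRelationship:
    midline_deviation: float  # x: upper minus lower incisal
    overbite: float  # y: lower minus upper incisal (positive = overlap)
    overjet: float  # z: upper minus lower incisal (positive = upper forward)
    molar_relationship_r: np.ndarray | None = None  # UMcusp - LMcusp, per axis
    molar_relationship_l: np.ndarray | None = None

    @property
    def overbite_desirable(self) -> bool:
        lo, hi = DESIRABLE_RANGE_MM
        return lo <= self.overbite <= hi

    @property
    def overjet_desirable(self) -> bool:
        lo, hi = DESIRABLE_RANGE_MM
        return lo <= self.overjet <= hi

    def as_dict(self) -> dict:
        d = {
            "midline_deviation": self.midline_deviation,
            "overbite": self.overbite,
            "overjet": self.overjet,
            "overbite_desirable": self.overbite_desirable,
            "overjet_desirable": self.overjet_desirable,
        }
        if self.molar_relationship_r is not None:
            d["molar_relationship_r"] = list(self.molar_relationship_r)
        if self.molar_relationship_l is not None:
            d["molar_relationship_l"] = list(self.molar_relationship_l)
        return d


@dataclass
class ToleranceInterval:
    mean_abs_diff: float
    sd: float
    low: float
    high: float
    coverage: float
    passes: bool  # coverage >= 0.68


@dataclass
class ICCResult:
    icc: float
    band: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    degenerate: bool = False


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    table: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------


def maxillary_movement(landmarks: LandmarkSet, T: RigidTransform) -> MovementDelta:
    """Displacement T(p) − p at UI, UMcusp_r and UMcusp_l."""
    landmarks.require(*MOVEMENT_LANDMARKS)
    return MovementDelta(
        deltas={n: T.apply(landmarks[n]) - landmarks[n] for n in MOVEMENT_LANDMARKS}
    )


def jaw_relationship(landmarks: LandmarkSet) -> JawRelationship:
    """Inter-jaw relationship from (already positioned) landmark coordinates.

    midline = x(UI) − x(LI); overbite = y(LI) − y(UI);
    overjet = z(UI) − z(LI); molar relationships upper-minus-lower per axis.
    Invariant under rigid motion of both jaws together (translations
    exactly; differences are coordinate-wise).
    """
    landmarks.require("UI", "LI")
    ui, li = landmarks["UI"], landmarks["LI"]
    rel = JawRelationship(
        midline_deviation=float(ui[0] - li[0]),
        overbite=float(li[1] - ui[1]),
        overjet=float(ui[2] - li[2]),
    )
    if landmarks.UMcusp_r is not None and landmarks.LMcusp_r is not None:
        rel.molar_relationship_r = landmarks["UMcusp_r"] - landmarks["LMcusp_r"]
    if landmarks.UMcusp_l is not None and landmarks.LMcusp_l is not None:
        rel.molar_relationship_l = landmarks["UMcusp_l"] - landmarks["LMcusp_l"]
    return rel


def tolerance_interval(
    gold_diffs: np.ndarray,
    test_diffs: np.ndarray,
    use_absolute: bool = True,
) -> ToleranceInterval:
    """Clinical acceptability band from gold-standard inter-observer spread.

    The interval is mean ± 1 SD of the absolute gold differences, floored at
    0; coverage is the fraction of absolute test differences inside it.
    ``use_absolute=False`` switches to the SD of signed differences (an
    alternative reading; the absolute form is the default).
    """
    gold = np.asarray(gold_diffs, dtype=np.float64)
    test = np.asarray(test_diffs, dtype=np.float64)
    if len(gold) < 2:
        raise ValueError("need at least two gold-standard differences")
    agold = np.abs(gold)
    mean = float(agold.mean())
    sd = float(agold.std(ddof=1) if use_absolute else gold.std(ddof=1))
    low = max(0.0, mean - sd)
    high = mean + sd
    atest = np.abs(test)
    coverage = float(((atest >= low) & (atest <= high)).mean()) if len(test) else 0.0
    return ToleranceInterval(mean, sd, low, high, coverage, coverage >= 0.68)


def _icc_band(icc: float) -> str:
    if icc > 0.90:
        return "very good"
    if icc >= 0.75:
        return "good"
    return "poor"


def icc_absolute_agreement(table: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``table`` is subjects × raters with no missing cells.  Computed from the
    two-way ANOVA mean squares:

        ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)

    with MSR between subjects, MSC between raters, MSE residual.  A table
    with zero variance everywhere is perfect agreement by convention
    (ICC = 1, flagged degenerate).
    """
    x = np.asarray(table, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-30:
        return ICCResult(1.0, _icc_band(1.0), msr, msc, mse, degenerate=True)
    icc = float(np.clip((msr - mse) / denom, -1.0, 1.0))
    return ICCResult(icc, _icc_band(icc), float(msr), float(msc), float(mse))


def icc_from_table(
    df: pd.DataFrame,
    design: str = "inter",
    value_col: str = "value_mm",
) -> pd.DataFrame:
    """ICCs from a long measurement table.

    Expected columns: subject, observer, timepoint, method, landmark, axis,
    value_mm.  ``design='inter'`` compares observers (pooling time points as
    separate subjects-by-occasion rows); ``design='intra'`` compares time
    points separately per observer.  Returns one row per
    (method, landmark, axis [, observer]) with the ICC and band.
    """
    rows = []
    group_cols = ["method", "landmark", "axis"]
    for keys, g in df.groupby(group_cols):
        if design == "inter":
            wide = g.pivot_table(
                index=["subject", "timepoint"], columns="observer",
                values=value_col,
            ).dropna()
            res = icc_absolute_agreement(wide.to_numpy())
            rows.append(dict(zip(group_cols, keys)) | {
                "icc": res.icc, "band": res.band, "n": len(wide),
            })
        elif design == "intra":
            for obs, go in g.groupby("observer"):
                wide = go.pivot_table(
                    index="subject", columns="timepoint", values=value_col
                ).dropna()
                res = icc_absolute_agreement(wide.to_numpy())
                rows.append(dict(zip(group_cols, keys)) | {
                    "observer": obs, "icc": res.icc, "band": res.band,
                    "n": len(wide),
                })
        else:
            raise ValueError("design must be 'inter' or 'intra'")
    return pd.DataFrame(rows)


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Bland–Altman agreement of two paired measurement series.

    Differences a − b against their averages; limits of agreement at
    mean ± 1.96 SD.  The per-point (average, difference) table supports the
    conventional plot.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    table = pd.DataFrame({"average": (a + b) / 2.0, "difference": diff})
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - LOA_FACTOR * sd_diff,
        loa_high=mean_diff + LOA_FACTOR * sd_diff,
        table=table,
    )
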