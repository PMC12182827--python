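"""Fetal hemodynamic indexing and automated-vs-manual flow comparison.

Vessel flows (mL/min) measured on the 2D PC acquisitions are indexed to the
estimated fetal weight (EFW), giving mL/kg/min values comparable against
published gestational reference ranges.  EFW is an affine function of the
segmented fetal body volume:

    EFW [g] = volume [mL] * 1.031 + 120

Paired automated/manual acquisitions of the same vessel in the same fetus
are compared by the percentage difference of their (unrounded) indexed
flows, Δ = (manual − automated) / manual × 100.

A fixture CSV with the published prospective-cohort measurements (four
fetuses, thirteen acquisitions) ships with the package; see
:func:`cohort_flow_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidInputError

EFW_SLOPE_G_PER_ML = 1.031
EFW_INTERCEPT_G = 120.0


@dataclass(frozen=True)
class ReferenceRange:
    """Published indexed-flow reference interval, mL/kg/min (inclusive)."""

    vessel: str
    low: float
    high: float
    source: str = "literature"

    def __post_init__(self):
        if not self.low < self.high:
            raise InvalidInputError("reference range requires low < high")


#: Late-gestation reference ranges used in the prospective comparison.
DEFAULT_REFERENCE_RANGES: dict[str, ReferenceRange] = {
    "DAo": ReferenceRange("DAo", 160.0, 344.0),
    "UV": ReferenceRange("UV", 62.0, 206.0),
}


@dataclass(frozen=True)
class FlowMeasurement:
    """One PC flow acquisition of one vessel in one fetus."""

    case_id: str
    vessel: str
    method: str  # "automated" | "manual"
    flow_mL_min: float
    efw_kg: float

    def __post_init__(self):
        if self.flow_mL_min < 0:
            raise InvalidInputError("flow must be >= 0")
        if self.efw_kg <= 0:
            raise InvalidInputError("EFW must be > 0")

    @property
    def indexed_mL_kg_min(self) -> float:
        return indexed_flow(self.flow_mL_min, self.efw_kg)


@dataclass(frozen=True)
class PairedDelta:
    """An automated acquisition paired with its manual counterpart."""

    automated: FlowMeasurement
    manual: FlowMeasurement

    def __post_init__(self):
        if (self.automated.case_id, self.automated.vessel) != (
            self.manual.case_id,
            self.manual.vessel,
        ):
            raise InvalidInputError("paired measurements must share case and vessel")
        if self.automated.method == self.manual.method:
            raise InvalidInputError("a pair needs one automated and one manual scan")

    @property
    def case_id(self) -> str:
        return self.automated.case_id

    @property
    def vessel(self) -> str:
        return self.automated.vessel

    @property
    def delta_pct(self) -> float:
        return percent_difference(self)


def estimate_fetal_weight(volume_mL: float) -> float:
    """EFW in kg from fetal body volume in mL (affine, grams internally)."""
    if volume_mL < 0:
        raise InvalidInputError("fetal volume must be >= 0")
    return (volume_mL * EFW_SLOPE_G_PER_ML + EFW_INTERCEPT_G) / 1000.0


def indexed_flow(flow_mL_min: float, efw_kg: float) -> float:
    """Flow indexed to fetal weight, mL/kg/min (unrounded)."""
    if efw_kg <= 0:
        raise InvalidInputError("EFW must be > 0")
    return flow_mL_min / efw_kg


def round_indexed(indexed: float) -> int:
    """Integer reporting convention for indexed flows (round half up)."""
    return int(np.floor(indexed + 0.5))


def classify_reference_range(
    vessel: str,
    indexed: float,
    ranges: dict[str, ReferenceRange] | None = None,
) -> str:
    """'below' | 'within' | 'above' the vessel's reference interval
    (bounds inclusive)."""
    ranges = DEFAULT_REFERENCE_RANGES if ranges is None else ranges
    if vessel not in ranges:
        raise InvalidInputError(f"no reference range for vessel {vessel!r}")
    r = ranges[vessel]
    if indexed < r.low:
        return "below"
    if indexed > r.high:
        return "above"
    return "within"


def percent_difference(pair: PairedDelta) -> float:
    """Δ = (manual − automated) / manual × 100, on unrounded indexed flows."""
    man = pair.manual.indexed_mL_kg_min
    auto = pair.automated.indexed_mL_kg_min
    if man == 0:
        raise InvalidInputError("manual indexed flow is zero")
    return (man - auto) / man * 100.0


def cohort_summary(pairs: list[PairedDelta]) -> tuple[float, float, float]:
    """(mean, min, max) of the paired percentage differences."""
    if not pairs:
        raise InvalidInputError("cohort summary needs at least one pair")
    deltas = [p.delta_pct for p in pairs]
    return float(np.mean(deltas)), float(min(deltas)), float(max(deltas))


def pair_measurements(measurements: list[FlowMeasurement]) -> list[PairedDelta]:
    """Pair every automated scan with each manual scan of the same
    (case, vessel); cells lacking either method yield no pair."""
    pairs: list[PairedDelta] = []
    keys = sorted({(m.case_id, m.vessel) for m in measurements})
    for key in keys:
        cell = [m for m in measurements if (m.case_id, m.vessel) == key]
        autos = [m for m in cell if m.method == "automated"]
        mans = [m for m in cell if m.method == "manual"]
        for a in autos:
            for m in mans:
                pairs.append(PairedDelta(a, m))
    return pairs


# ---------------------------------------------------------------------------
# CSV interfaces


def load_flow_csv(path) -> list[FlowMeasurement]:
    """Read measurements from CSV.

    Required columns: case_id, vessel, method, flow_mL_min, and one of
    efw_kg or fetal_volume_mL (EFW derived from volume when absent).
    """
    df = pd.read_csv(path)
    required = {"case_id", "vessel", "method", "flow_mL_min"}
    if not required <= set(df.columns):
        raise InvalidInputError(f"flow CSV needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        if "efw_kg" in df.columns and pd.notna(row.get("efw_kg")):
            efw = float(row["efw_kg"])
        elif "fetal_volume_mL" in df.columns and pd.notna(row.get("fetal_volume_mL")):
            efw = estimate_fetal_weight(float(row["fetal_volume_mL"]))
        else:
            raise InvalidInputError(
                f"row {row['case_id']}/{row['vessel']}: no efw_kg or fetal_volume_mL"
            )
        out.append(
            FlowMeasurement(
                case_id=str(row["case_id"]),
                vessel=str(row["vessel"]),
                method=str(row["method"]).lower(),
                flow_mL_min=float(row["flow_mL_min"]),
                efw_kg=efw,
            )
        )
    return out


def cohort_flow_table() -> pd.DataFrame:
    """The packaged prospective-cohort flow table.

    Columns ``indexed_printed`` and ``delta_printed`` carry the values as
    published (integers / one decimal); everything else is input data.
    """
    with resources.files("fetalplan").joinpath(
        "data/prospective_flows.csv"
    ).open() as fh:
        return pd.read_csv(fh, dtype={"case_id": str})


def analyze_flows(
    measurements: list[FlowMeasurement],
    ranges: dict[str, ReferenceRange] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full flow report: per-scan indexed values + verdicts, per-pair Δ,
    cohort summary dict."""
    rows = [
        {
            "case_id": m.case_id,
            "vessel": m.vessel,
            "method": m.method,
            "flow_mL_min": m.flow_mL_min,
            "efw_kg": m.efw_kg,
            "indexed_mL_kg_min": round_indexed(m.indexed_mL_kg_min),
            "verdict": classify_reference_range(m.vessel, m.indexed_mL_kg_min, ranges),
        }
        for m in measurements
    ]
    pairs = pair_measurements(measurements)
    pair_rows = [
        {
            "case_id": p.case_id,
            "vessel": p.vessel,
            "automated_flow": p.automated.flow_mL_min,
            "manual_flow": p.manual.flow_mL_min,
            "delta_pct": round(p.delta_pct, 1),
        }
        for p in pairs
    ]
    summary = {}
    if pairs:
        mean, lo, hi = cohort_summary(pairs)
        summary = {
            "n_pairs": len(pairs),
            "mean_delta_pct": round(mean, 1),
            "min_delta_pct": round(lo, 1),
            "max_delta_pct": round(hi, 1),
        }
    return pd.DataFrame(rows), pd.DataFrame(pair_rows), summary
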