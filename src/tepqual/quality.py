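"""Stage-wise tomato fruit-quality measurements and the CIELAB color index.

A quality record is one treatment x ripening-stage observation of the seven
indices used throughout the package: color index (CI), fruit firmness,
soluble sugar (SSC), organic acid (OAC), the sugar-acid ratio SSC/OAC,
lycopene and vitamin C, together with the cumulative TEP at sampling.

The in-study calibration tables ship as packaged CSV fixtures: stage-wise
means with replicate standard deviations (``table5``), the red-ripening
batch comparison (``table2``), the published correlation row (``table6``),
the two hierarchical weight tables (``table3``, ``table8``) and the
comprehensive TOPSIS scores (``table9``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import InputError
from .mcdm import WeightVector

CRITERIA = ("ci", "firmness", "ssc", "oac", "ssc_oac", "lycopene", "vc")

_CSV_COLUMNS = [
    "treatment", "stage", "tep_mj_m2", "l_star", "a_star", "b_star", "ci",
    "ssc_g100g", "oac_g100g", "ssc_oac", "vc_mg100g", "lycopene_mgkg",
    "firmness_kgcm2",
]


class RipeningStage(enum.IntEnum):
    """Ordered ripening stages: mature green, three veraison samplings, red ripe."""

    GM = 0
    V1 = 1
    V2 = 2
    V3 = 3
    RR = 4

    @classmethod
    def from_string(cls, text: str) -> "RipeningStage":
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise InputError(f"unknown ripening stage {text!r}") from None


@dataclass(frozen=True)
class ColorMeasurement:
    """CIELAB coordinates of the fruit surface (L* lightness, a* red-green, b* yellow-blue)."""

    l_star: float
    a_star: float
    b_star: float

    def __post_init__(self):
        if not self.l_star > 0:
            raise InputError(f"l_star must be positive, got {self.l_star}")

    @property
    def index(self) -> float:
        return color_index(self.l_star, self.a_star, self.b_star)


def color_index(l_star, a_star, b_star):
    """Scalar ripeness-color summary CI = 2000 a* / (L* sqrt(a*^2 + b*^2)).

    Negative for green fruit (a* < 0) and increasingly positive as red
    pigment accumulates.  Accepts scalars or arrays.
    """
    l_star = np.asarray(l_star, dtype=float)
    a_star = np.asarray(a_star, dtype=float)
    b_star = np.asarray(b_star, dtype=float)
    if np.any(l_star <= 0):
        raise InputError("l_star must be positive")
    chroma = np.hypot(a_star, b_star)
    if np.any(chroma == 0):
        raise InputError("a* and b* cannot both be zero")
    out = 2000.0 * a_star / (l_star * chroma)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class QualityRecord:
    """One treatment x stage fruit-quality observation.

    ``tep`` is the cumulative TEP (MJ m-2) at sampling; it may be None for
    tables that do not report it.  ``sd`` carries replicate standard
    deviations keyed by field name where published.  ``comprehensive`` is
    the TOPSIS score when the source table prints one.
    """

    treatment: str
    stage: RipeningStage
    ssc: float
    oac: float
    vc: float
    lycopene: float
    firmness: float
    tep: float | None = None
    color: ColorMeasurement | None = None
    ci: float | None = None
    ssc_oac: float | None = None
    comprehensive: float | None = None
    sd: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("ssc", "oac", "vc", "lycopene", "firmness"):
            value = getattr(self, name)
            if not value > 0:
                raise InputError(f"{name} must be positive, got {value}")
        if self.tep is not None and not self.tep > 0:
            raise InputError(f"tep must be positive, got {self.tep}")
        if self.ssc_oac is None:
            object.__setattr__(self, "ssc_oac", self.ssc / self.oac)
        if self.ci is None and self.color is not None:
            object.__setattr__(self, "ci", self.color.index)

    @property
    def label(self) -> str:
        return f"{self.treatment}-{self.stage.name}"


def records_to_frame(records) -> pd.DataFrame:
    """Criteria matrix (options x 7 indices) for the MCDM stage, labelled rows."""
    rows = {}
    for rec in records:
        rows[rec.label] = {
            "ci": rec.ci, "firmness": rec.firmness, "ssc": rec.ssc,
            "oac": rec.oac, "ssc_oac": rec.ssc_oac,
            "lycopene": rec.lycopene, "vc": rec.vc,
            **({"tep": rec.tep} if rec.tep is not None else {}),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _data_path(filename: str):
    return resources.files("tepqual.data").joinpath(filename)


def _quality_records_from_frame(frame: pd.DataFrame, has_tep: bool) -> list[QualityRecord]:
    records = []
    for _, row in frame.iterrows():
        sd = {
            key: row[f"{col}_sd"]
            for key, col in [
                ("l_star", "l_star"), ("a_star", "a_star"), ("b_star", "b_star"),
                ("ci", "ci"), ("ssc", "ssc"), ("oac", "oac"), ("vc", "vc"),
                ("lycopene", "lycopene"), ("firmness", "firmness"),
            ]
            if f"{col}_sd" in row.index and pd.notna(row[f"{col}_sd"])
        }
        records.append(
            QualityRecord(
                treatment=row["treatment"],
                stage=RipeningStage.from_string(row["stage"]),
                tep=row["tep_mj_m2"] if has_tep else None,
                color=ColorMeasurement(row["l_star"], row["a_star"], row["b_star"]),
                ci=row["ci"],
                ssc=row["ssc_g100g"],
                oac=row["oac_g100g"],
                ssc_oac=row["ssc_oac"],
                vc=row["vc_mg100g"],
                lycopene=row["lycopene_mgkg"],
                firmness=row["firmness_kgcm2"],
                comprehensive=row.get("comprehensive"),
                sd=sd,
            )
        )
    return records


def _load_weight_table(filename: str) -> dict:
    frame = pd.read_csv(_data_path(filename))
    factors = frame.drop_duplicates("factor")
    out = {
        "factors": WeightVector(
            tuple(factors["factor"]), factors["factor_weight"].to_numpy(), atol=5e-3
        ),
        "subfactors": {},
        "combined": WeightVector(
            tuple(frame["criterion"]), frame["combined_weight"].to_numpy(), atol=5e-3
        ),
    }
    for name, group in frame.groupby("factor", sort=False):
        out["subfactors"][name] = WeightVector(
            tuple(group["criterion"]), group["sub_weight"].to_numpy(), atol=5e-3
        )
    return out


def load_fixture_table(name: str):
    """Return a packaged calibration table.

    ``table2``/``table5`` -> list of :class:`QualityRecord`;
    ``table3``/``table8`` -> dict of factor / sub-factor / combined
    :class:`~tepqual.mcdm.WeightVector`; ``table6`` -> Series of Pearson r
    against TEP; ``table9`` -> DataFrame of comprehensive TOPSIS scores.
    """
    if name == "table5":
        frame = pd.read_csv(_data_path("table5_quality.csv"))
        return _quality_records_from_frame(frame, has_tep=True)
    if name == "table2":
        frame = pd.read_csv(_data_path("table2_quality.csv"))
        return _quality_records_from_frame(frame, has_tep=False)
    if name == "table6":
        frame = pd.read_csv(_data_path("table6_correlations.csv"))
        return frame.set_index("criterion")["r"]
    if name in ("table3", "table8"):
        return _load_weight_table(f"{name}_weights.csv")
    if name == "table9":
        return pd.read_csv(_data_path("table9_comprehensive.csv"))
    raise LookupError(f"unknown fixture table {name!r}")


def paired_comprehensive_data() -> tuple[np.ndarray, np.ndarray]:
    """The 21 (TEP, comprehensive score) calibration pairs, stage-matched."""
    records = {(r.treatment, r.stage.name): r.tep for r in load_fixture_table("table5")}
    table9 = load_fixture_table("table9")
    tep = np.array([records[(row.treatment, row.stage)] for row in table9.itertuples()])
    return tep, table9["comprehensive"].to_numpy()


def validate_quality_csv(path) -> list[QualityRecord]:
    """Parse and validate a quality CSV, reporting offending row numbers.

    Expected columns follow the fixture schema; ``ssc_oac`` is recomputed
    from SSC/OAC when absent.
    """
    frame = pd.read_csv(path)
    required = set(_CSV_COLUMNS) - {"ssc_oac", "ci"}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"quality CSV lacks columns: {sorted(missing)}")
    records, problems = [], []
    for i, row in frame.iterrows():
        try:
            records.append(
                QualityRecord(
                    treatment=row["treatment"],
                    stage=RipeningStage.from_string(row["stage"]),
                    tep=row["tep_mj_m2"],
                    color=ColorMeasurement(row["l_star"], row["a_star"], row["b_star"]),
                    ci=row["ci"] if "ci" in row.index and pd.notna(row["ci"]) else None,
                    ssc=row["ssc_g100g"],
                    oac=row["oac_g100g"],
                    ssc_oac=(
                        row["ssc_oac"]
                        if "ssc_oac" in row.index and pd.notna(row["ssc_oac"])
                        else None
                    ),
                    vc=row["vc_mg100g"],
                    lycopene=row["lycopene_mgkg"],
                    firmness=row["firmness_kgcm2"],
                )
            )
        except (InputError, ZeroDivisionError) as exc:
            problems.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if problems:
        raise InputError("invalid quality CSV: " + "; ".join(problems))
    return records


def write_quality_csv(records, path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "treatment": rec.treatment,
                "stage": rec.stage.name,
                "tep_mj_m2": rec.tep,
                "l_star": rec.color.l_star if rec.color else np.nan,
                "a_star": rec.color.a_star if rec.color else np.nan,
                "b_star": rec.color.b_star if rec.color else np.nan,
                "ci": rec.ci,
                "ssc_g100g": rec.ssc,
                "oac_g100g": rec.oac,
                "ssc_oac": rec.ssc_oac,
                "vc_mg100g": rec.vc,
                "lycopene_mgkg": rec.lycopene,
                "firmness_kgcm2": rec.firmness,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
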