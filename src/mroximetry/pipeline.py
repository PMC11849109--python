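"""Per-subject orchestration into the regional table, and the group stage.

``run_subject`` chains the measurement stages — voxel-wise kinetic fitting,
territory aggregation of the CBF/ATT maps, vein oximetry on the
susceptibility map, end-tidal SaO2, then OEF and CMRO2 — into one row per
venous territory. Any stage failure is recorded per territory and the run
continues for the remaining territories; missing territories propagate as
missing rows, never as imputed values.

The group stage is deliberately thin glue over established mixed-effects
machinery: a random intercept per subject with the predictor and territory
as fixed effects. Only coefficient recovery matters here; inference
(type-III ANOVA, p-values) is read off the fitted model when needed, not
re-implemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import EmptyRegionError
from .kinetics import AcquisitionSchedule, fit_volume
from .oxygen import (RespiratoryTrace, arterial_oxygen_from_trace, compute_cmro2,
                     compute_oef)
from .qsm import OximetryConstants, measure_vein
from .territories import VeinTerritoryAtlas, aggregate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SubjectInputs", "GroupModelResult",
           "run_subject", "fit_group_model", "predicted_change"]

REGIONAL_COLUMNS = ("subject", "session", "territory", "OEF", "CBF", "ATT",
                    "CMRO2", "SvO2", "SaO2")


@dataclass(frozen=True)
class PipelineConfig:
    """Serialisable description of one pipeline run."""

    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule.default)
    alpha: float = 0.85
    lam: float = 0.9
    oximetry: OximetryConstants = field(default_factory=OximetryConstants)
    lower_ppb: float = 130.0
    upper_ppb: float = 1000.0
    percentile: float = 90.0
    barometric_mmhg: float = 760.0
    water_vapour_mmhg: float = 47.0
    et_prominence: float = 0.5
    et_min_interval_s: float = 1.5

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = {"label_durations": list(self.schedule.label_durations),
                         "post_label_delays": list(self.schedule.post_label_delays)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "schedule" in d:
            d["schedule"] = AcquisitionSchedule(
                tuple(d["schedule"]["label_durations"]),
                tuple(d["schedule"]["post_label_delays"]))
        if "oximetry" in d and isinstance(d["oximetry"], dict):
            d["oximetry"] = OximetryConstants(**d["oximetry"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SubjectInputs:
    """In-memory inputs for one subject session."""

    subject: str
    asl_volumes: np.ndarray  # (X, Y, Z, n_delays)
    m0_volume: np.ndarray
    brain_mask: np.ndarray
    chi_ppm: np.ndarray
    vein_seeds: dict[str, np.ndarray]  # vein name -> boolean seed ROI
    parcellation: np.ndarray
    atlas: VeinTerritoryAtlas
    resp_trace: RespiratoryTrace
    hct: float
    session: int = 1


def run_subject(inputs: SubjectInputs,
                config: PipelineConfig | None = None) -> pd.DataFrame:
    """Full measurement chain for one subject session.

    Returns one row per vein territory with OEF, CBF, ATT, CMRO2 (plus the
    intermediate SvO2/SaO2). Territories whose vein ROI or parcellation
    region fails any stage get NaN values, with the reason logged; the other
    territories are unaffected.
    """
    config = config or PipelineConfig()

    cbf_map, att_map = fit_volume(inputs.asl_volumes, inputs.m0_volume,
                                  inputs.brain_mask, config.schedule,
                                  inputs.hct, alpha=config.alpha,
                                  lam=config.lam)

    art = arterial_oxygen_from_trace(
        inputs.resp_trace, inputs.hct,
        barometric=config.barometric_mmhg,
        water_vapour=config.water_vapour_mmhg,
        min_prominence=config.et_prominence,
        min_breath_interval_s=config.et_min_interval_s)

    rows = []
    for vein in inputs.atlas.veins:
        row = {"subject": inputs.subject, "session": inputs.session,
               "territory": vein, "OEF": np.nan, "CBF": np.nan,
               "ATT": np.nan, "CMRO2": np.nan, "SvO2": np.nan,
               "SaO2": art.sao2}
        try:
            labels = inputs.atlas.compose(vein)
            row["CBF"] = aggregate(cbf_map, inputs.parcellation, labels)
            row["ATT"] = aggregate(att_map, inputs.parcellation, labels)
            seed = inputs.vein_seeds[vein]
            vm = measure_vein(vein, seed, inputs.chi_ppm, inputs.hct,
                              constants=config.oximetry,
                              lower_ppb=config.lower_ppb,
                              upper_ppb=config.upper_ppb,
                              percentile=config.percentile)
            row["SvO2"] = vm.svo2
            row["OEF"] = compute_oef(art.sao2, vm.svo2)
            row["CMRO2"] = compute_cmro2(row["CBF"], art.o2a, row["OEF"])
        except (EmptyRegionError, KeyError, ValueError) as exc:
            logger.warning("subject %s territory %s: %s",
                           inputs.subject, vein, exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(REGIONAL_COLUMNS))


class GroupModelResult:
    """Coefficient table of the group mixed model (or its OLS fallback)."""

    def __init__(self, outcome: str, predictor: str, params: pd.Series,
                 bse: pd.Series, method: str, converged: bool,
                 diagnostics: str = ""):
        self.outcome = outcome
        self.predictor = predictor
        self.params = params
        self.bse = bse
        self.method = method
        self.converged = converged
        self.diagnostics = diagnostics

    @property
    def slope(self) -> float:
        """Fixed-effect coefficient of the predictor."""
        return float(self.params[self.predictor])

    @property
    def slope_se(self) -> float:
        return float(self.bse[self.predictor])

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse})

    def summary(self) -> str:
        lines = [f"Group model: {self.outcome} ~ {self.predictor} + territory"
                 f" (+ random intercept per subject)",
                 f"  method    : {self.method}",
                 f"  converged : {self.converged}"]
        if self.diagnostics:
            lines.append(f"  note      : {self.diagnostics}")
        lines.append(self.coefficient_table().to_string(float_format="%.4f"))
        return "\n".join(lines)


def fit_group_model(table: pd.DataFrame, outcome: str, predictor: str,
                    subject_col: str = "subject",
                    territory_col: str = "territory") -> GroupModelResult:
    """Linear mixed model of a regional outcome on a subject-level predictor.

    Fixed effects: the predictor and territory; random intercept per
    subject. When every subject contributes a single observation the random
    intercept is unidentifiable and the model reduces to ordinary least
    squares, which is then used directly. A singular or non-converged mixed
    fit likewise falls back to OLS with the reason recorded in
    ``diagnostics`` rather than crashing.
    """
    import statsmodels.formula.api as smf

    data = table.dropna(subset=[outcome, predictor]).copy()
    if data[subject_col].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    data = data.rename(columns={outcome: "_y", predictor: "_x",
                                territory_col: "_territory"})
    multiple_territories = data["_territory"].nunique() > 1
    formula = "_y ~ _x + C(_territory)" if multiple_territories else "_y ~ _x"

    obs_per_subject = data.groupby(subject_col).size()
    if (obs_per_subject == 1).all():
        res = smf.ols(formula, data=data).fit()
        return GroupModelResult(outcome, predictor,
                                res.params.rename({"_x": predictor}),
                                res.bse.rename({"_x": predictor}),
                                method="ols", converged=True,
                                diagnostics="one observation per subject; "
                                            "random intercept unidentifiable")

    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, data=data,
                              groups=data[subject_col]).fit(reml=True)
        converged = bool(getattr(res, "converged", True))
        if converged:
            return GroupModelResult(outcome, predictor,
                                    res.params.rename({"_x": predictor}),
                                    res.bse.rename({"_x": predictor}),
                                    method="mixedlm", converged=True)
        diagnostics = "mixed model did not converge; OLS fallback"
    except (np.linalg.LinAlgError, ValueError) as exc:
        diagnostics = f"mixed model singular ({exc}); OLS fallback"

    res = smf.ols(formula, data=data).fit()
    return GroupModelResult(outcome, predictor,
                            res.params.rename({"_x": predictor}),
                            res.bse.rename({"_x": predictor}),
                            method="ols", converged=False,
                            diagnostics=diagnostics)


def predicted_change(coefficient: float, delta: float) -> float:
    """Predicted outcome change for a ``delta``-point predictor increase."""
    if not (np.isfinite(coefficient) and np.isfinite(delta)):
        raise ValueError("coefficient and delta must be finite")
    return coefficient * delta
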