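"""Synthetic cohorts, phantoms and traces for exercising the pipeline.

No imaging data accompany the study design this pipeline targets, so every
stage is tested against generated inputs that carry the statistical
structure the analysis assumes:

* a cohort whose territory ATT depends linearly on the QRisk vascular-risk
  score plus a per-subject random offset, with territory means seeded from
  documented regional constants;
* 4-D ASL difference volumes that are exact forward evaluations of the
  kinetic model at each voxel's territory truth, plus additive Gaussian
  noise on the difference signal (difference images are approximately
  Gaussian-distributed);
* cylindrical vein phantoms whose core susceptibility is the exact forward
  value of the oximetry relation, with linear partial-volume blending at the
  cylinder edge;
* trapezoidal respiratory traces whose end-expiratory plateaus sit exactly
  at the requested end-tidal O2 percentage.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import AcquisitionSchedule, KineticConstants, pcasl_signal
from .oxygen import RespiratoryTrace
from .qsm import OximetryConstants, susceptibility_from_svo2
from .territories import VeinTerritoryAtlas

__all__ = [
    "TERRITORIES",
    "TERRITORY_MEANS",
    "GroundTruthSubject",
    "PhantomSpec",
    "make_cohort",
    "cohort_to_frame",
    "make_parcellation_phantom",
    "simulate_asl_volume",
    "simulate_susceptibility_phantom",
    "simulate_resp_trace",
]

TERRITORIES = ("SSS V", "SSS H", "SS", "BVs", "ICVs")

# Documented regional constants seeding the generator (means and standard
# errors of a 24-subject cohort). OEF in percent, CBF in ml/100 ml/min,
# ATT in ms.
TERRITORY_MEANS = {
    "ATT": {"SSS V": 1592.0, "SSS H": 1497.0, "SS": 1399.0,
            "BVs": 1102.0, "ICVs": 1183.0},
    "CBF": {"SSS V": 43.0, "SSS H": 44.2, "SS": 34.4,
            "BVs": 39.6, "ICVs": 36.2},
    "OEF": {"SSS V": 42.7, "SSS H": 44.5, "SS": 46.5,
            "BVs": 34.9, "ICVs": 37.7},
}
_STDERR = {"ATT": 48.6, "CBF": 1.8, "OEF": 0.8}
_N_REFERENCE = 24  # cohort size behind the standard errors above

# observed QRisk range of the reference cohort, percent
QRISK_RANGE = (5.1, 45.4)
QRISK_CENTRE = 0.5 * (QRISK_RANGE[0] + QRISK_RANGE[1])

# per-subject offset SDs: standard error * sqrt(n)
_SUBJECT_SD = {k: v * np.sqrt(_N_REFERENCE) for k, v in _STDERR.items()}


@dataclass(frozen=True)
class GroundTruthSubject:
    """Generating truth for one synthetic participant."""

    subject_id: str
    hct: float  # volume fraction
    qrisk: float  # percent 10-year risk score
    moca: int  # 0-30
    amyloid_status: bool
    cbf: dict[str, float] = field(repr=False)  # ml/100 ml/min per territory
    att: dict[str, float] = field(repr=False)  # ms per territory
    svo2: dict[str, float] = field(repr=False)  # fraction per territory
    sao2_truth: float = 0.98

    def __post_init__(self) -> None:
        if not 0.0 < self.hct < 1.0:
            raise ValueError("hct must lie in (0, 1)")
        if not 0.0 < self.sao2_truth <= 1.0:
            raise ValueError("sao2_truth must lie in (0, 1]")
        for t, v in self.svo2.items():
            if not 0.0 <= v < self.sao2_truth:
                raise ValueError(f"SvO2[{t}] must lie in [0, sao2_truth)")


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic geometry and noise description of an image phantom."""

    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 1.0
    vein_radius: float = 2.5  # voxels
    vein_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_sd: float = 0.0  # units of the field it perturbs
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive voxel counts")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        axis = np.asarray(self.vein_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("vein_axis must be a non-zero vector")
        object.__setattr__(self, "vein_axis", tuple(axis / norm))


def make_cohort(n: int, effect_slope: float = 13.2, seed: int = 0,
                att_subject_sd: float | None = None) -> list[GroundTruthSubject]:
    """Generate ``n`` synthetic subjects with QRisk-dependent ATT truth.

    Per territory, truth ATT is ``baseline + effect_slope * qrisk +
    subject_offset``; baselines are chosen so territory means sit at the
    documented regional constants when QRisk sits at the centre of its
    sampled range. QRisk is uniform on [5.1, 45.4]. Subject offsets are
    Gaussian, shared across territories (one global offset per subject and
    parameter), with SDs derived from the regional standard errors.

    Parameters
    ----------
    effect_slope : ms of ATT per QRisk point (default 13.2).
    att_subject_sd : override of the ATT subject-offset SD, ms.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    att_sd = _SUBJECT_SD["ATT"] if att_subject_sd is None else att_subject_sd

    subjects = []
    for i in range(n):
        qrisk = float(rng.uniform(*QRISK_RANGE))
        hct = float(np.clip(rng.normal(0.42, 0.03), 0.33, 0.52))
        moca = int(np.clip(round(rng.normal(26.7, 3.4)), 17, 30))
        amyloid = bool(rng.random() < 7 / 24)
        sao2 = float(np.clip(rng.normal(0.98, 0.004), 0.95, 0.999))

        att_off = float(rng.normal(0.0, att_sd))
        cbf_off = float(rng.normal(0.0, _SUBJECT_SD["CBF"]))
        # OEF offset in percent -> SvO2 offset in fraction
        svo2_off = float(rng.normal(0.0, _SUBJECT_SD["OEF"] / 100.0)) * sao2

        att = {
            t: float(np.clip(
                TERRITORY_MEANS["ATT"][t] - effect_slope * QRISK_CENTRE
                + effect_slope * qrisk + att_off, 200.0, 3400.0))
            for t in TERRITORIES
        }
        cbf = {
            t: float(np.clip(TERRITORY_MEANS["CBF"][t] + cbf_off, 5.0, 150.0))
            for t in TERRITORIES
        }
        svo2 = {
            t: float(np.clip(
                sao2 * (1.0 - TERRITORY_MEANS["OEF"][t] / 100.0) + svo2_off,
                0.2, sao2 - 0.01))
            for t in TERRITORIES
        }
        subjects.append(GroundTruthSubject(
            subject_id=f"sub-{i + 1:03d}", hct=hct, qrisk=qrisk, moca=moca,
            amyloid_status=amyloid, cbf=cbf, att=att, svo2=svo2,
            sao2_truth=sao2))
    return subjects


def cohort_to_frame(subjects: list[GroundTruthSubject]) -> pd.DataFrame:
    """Long-format truth table: one row per (subject, territory)."""
    rows = []
    for s in subjects:
        for t in TERRITORIES:
            rows.append({
                "subject": s.subject_id, "territory": t, "hct": s.hct,
                "qrisk": s.qrisk, "moca": s.moca,
                "amyloid_status": s.amyloid_status,
                "sao2_truth": s.sao2_truth, "cbf_truth": s.cbf[t],
                "att_truth": s.att[t], "svo2_truth": s.svo2[t],
            })
    return pd.DataFrame(rows)


# inter-session measurement CoVs of the observed order, percent of the mean
DEFAULT_MEASUREMENT_COV = {"ATT": 6.5, "CBF": 11.0, "SvO2": 3.0}


def simulate_regional_table(subjects: list[GroundTruthSubject], seed: int = 0,
                            sessions: int = 1,
                            measurement_cov: dict[str, float] | None = None
                            ) -> pd.DataFrame:
    """Noisy regional measurements of a cohort, bypassing the image stage.

    Adds independent Gaussian measurement error to each subject's territory
    truth, with SD equal to ``measurement_cov[param]/100`` of the territory
    mean — the scale of the observed inter-session coefficients of
    variation. One row per (subject, session, territory) with measured ATT,
    CBF, SvO2 plus derived OEF and CMRO2; used for scaled-down study
    replicates where simulating and fitting image volumes per subject is
    not the quantity under test.
    """
    from .oxygen import arterial_o2_content, compute_cmro2, compute_oef

    cov = dict(DEFAULT_MEASUREMENT_COV)
    if measurement_cov:
        cov.update(measurement_cov)
    rng = np.random.default_rng(seed)
    rows = []
    for session in range(1, sessions + 1):
        for s in subjects:
            o2a = arterial_o2_content(s.hct)
            for t in TERRITORIES:
                att = s.att[t] + rng.normal(
                    0.0, cov["ATT"] / 100.0 * TERRITORY_MEANS["ATT"][t])
                cbf = max(s.cbf[t] + rng.normal(
                    0.0, cov["CBF"] / 100.0 * TERRITORY_MEANS["CBF"][t]), 1.0)
                svo2 = float(np.clip(
                    s.svo2[t] + rng.normal(0.0, cov["SvO2"] / 100.0 * s.svo2[t]),
                    0.0, 1.0))
                with np.errstate(all="ignore"):
                    import warnings as _w

                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        oef = compute_oef(s.sao2_truth, svo2)
                rows.append({
                    "subject": s.subject_id, "session": session,
                    "territory": t, "qrisk": s.qrisk, "hct": s.hct,
                    "ATT": att, "CBF": cbf, "SvO2": svo2,
                    "OEF": oef,
                    "CMRO2": compute_cmro2(cbf, o2a, oef),
                })
    return pd.DataFrame(rows)


def make_parcellation_phantom(shape: tuple[int, int, int],
                              atlas: VeinTerritoryAtlas | None = None):
    """Integer parcellation volume covering every atlas label.

    Brain voxels (everything except a one-voxel border) are split into
    equal contiguous chunks, one per exclusive label, in sorted label
    order; background is 0. Returns ``(parcellation, brain_mask)``.
    """
    atlas = atlas or VeinTerritoryAtlas.default()
    labels = sorted(lab for labs in atlas.exclusive.values() for lab in labs)
    parc = np.zeros(shape, dtype=np.int32)
    mask = np.zeros(shape, dtype=bool)
    interior = tuple(slice(1, max(s - 1, 1)) for s in shape)
    mask[interior] = True
    idx = np.flatnonzero(mask.ravel())
    if idx.size < len(labels):
        raise ValueError("phantom too small to host every parcellation label")
    chunks = np.array_split(idx, len(labels))
    flat = parc.ravel()
    for lab, chunk in zip(labels, chunks):
        flat[chunk] = lab
    return parc, mask


def simulate_asl_volume(subject: GroundTruthSubject,
                        schedule: AcquisitionSchedule,
                        phantom: PhantomSpec,
                        parcellation: np.ndarray,
                        atlas: VeinTerritoryAtlas | None = None,
                        m0_value: float = 1000.0,
                        alpha: float = 0.85, lam: float = 0.9):
    """Forward-simulated multi-delay ASL difference volumes plus M0 volume.

    Each labelled voxel carries the exact kinetic-model signal of its
    territory's (CBF, ATT) truth, using the subject's haematocrit for the
    T1 of blood, with independent additive Gaussian noise of SD
    ``phantom.noise_sd * M0`` on every difference volume.
    """
    atlas = atlas or VeinTerritoryAtlas.default()
    parc = np.asarray(parcellation)
    constants = KineticConstants.for_hct(subject.hct, alpha=alpha, lam=lam)
    tau, w = schedule.tau, schedule.pld

    m0_vol = np.where(parc > 0, float(m0_value), 0.0)
    asl = np.zeros(parc.shape + (len(schedule),), dtype=float)
    for lab in np.unique(parc[parc > 0]):
        territory = atlas.vein_of_label(int(lab))  # raises on unknown label
        sig = pcasl_signal(subject.cbf[territory], subject.att[territory],
                           tau, w, constants, m0_value)
        asl[parc == lab] = sig
    if phantom.noise_sd > 0:
        rng = np.random.default_rng(phantom.seed)
        asl += rng.normal(0.0, phantom.noise_sd * m0_value, size=asl.shape)
    return asl, m0_vol


def simulate_susceptibility_phantom(svo2: float, hct: float,
                                    phantom: PhantomSpec,
                                    constants: OximetryConstants | None = None):
    """Cylindrical vein phantom on a zero background, in ppm.

    The cylinder runs through the grid centre along ``phantom.vein_axis``.
    Voxels fully inside the cylinder carry the exact forward susceptibility
    of the requested (SvO2, Hct); edge voxels are blended linearly in the
    occupied volume fraction to mimic partial volume. Optional Gaussian
    noise (SD ``phantom.noise_sd`` ppm) is added everywhere.

    Returns ``(chi_ppm, brain_mask, seed_roi, edge_fraction)`` where
    ``edge_fraction`` records the per-voxel blending weights.
    """
    if not 0.0 <= svo2 <= 1.0:
        raise ValueError("svo2 must lie in [0, 1]")
    if phantom.vein_radius <= 0:
        raise ValueError("vein radius must be > 0")
    constants = constants or OximetryConstants()
    chi_vein = susceptibility_from_svo2(svo2, hct, constants)

    shape = phantom.shape
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    axis = np.asarray(phantom.vein_axis, dtype=float)
    coords = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                  indexing="ij"), axis=-1) - centre
    along = coords @ axis
    radial = coords - along[..., None] * axis
    dist = np.linalg.norm(radial, axis=-1)

    frac = np.clip(phantom.vein_radius + 0.5 - dist, 0.0, 1.0)
    chi = frac * chi_vein
    if phantom.noise_sd > 0:
        rng = np.random.default_rng(phantom.seed)
        chi = chi + rng.normal(0.0, phantom.noise_sd, size=shape)
    brain_mask = np.ones(shape, dtype=bool)
    seed_roi = dist <= phantom.vein_radius + 1.0
    return chi, brain_mask, seed_roi, frac


def simulate_resp_trace(et_percent: float, breaths: int,
                        sampling_hz: float = 20.0, seed: int = 0,
                        inspired_percent: float = 20.9,
                        breath_period_s: float = 4.0) -> RespiratoryTrace:
    """Trapezoidal exhaled-O2 trace with exact end-tidal plateaus.

    Each breath ramps from an inspiratory plateau near ``inspired_percent``
    down to an end-expiratory plateau at exactly ``et_percent`` and back.
    Breath timing and the inspiratory level jitter with the seed; the
    end-tidal plateau samples are exact by construction.
    """
    if not 0.0 < et_percent < 21.0:
        raise ValueError("end-tidal O2 percent must lie in (0, 21)")
    if breaths < 3:
        raise ValueError("need at least 3 breaths for end-tidal extraction")
    if sampling_hz <= 0:
        raise ValueError("sampling rate must be > 0")
    rng = np.random.default_rng(seed)

    segments = []
    for _ in range(breaths):
        period = breath_period_s * float(rng.uniform(0.9, 1.1))
        insp_level = inspired_percent + float(rng.uniform(-0.1, 0.1))
        n_insp = max(2, int(round(0.30 * period * sampling_hz)))
        n_down = max(2, int(round(0.20 * period * sampling_hz)))
        n_et = max(3, int(round(0.30 * period * sampling_hz)))
        n_up = max(2, int(round(0.20 * period * sampling_hz)))
        segments.append(np.full(n_insp, insp_level))
        segments.append(np.linspace(insp_level, et_percent, n_down + 2)[1:-1])
        segments.append(np.full(n_et, et_percent))
        segments.append(np.linspace(et_percent, insp_level, n_up + 2)[1:-1])
    # close on an inspiratory plateau so the last end-tidal dip is a peak
    segments.append(np.full(4, inspired_percent))
    return RespiratoryTrace(samples=np.concatenate(segments),
                            sampling_hz=sampling_hz)
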