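"""Arterial oxygenation, OEF and CMRO2.

End-tidal O2 is read off the expiratory plateaus of the exhaled-gas trace
(local minima of O2 concentration — expiration lowers the O2 fraction),
converted to an alveolar partial pressure and then to arterial saturation
through the Severinghaus dissociation curve

    SaO2 = 1 / (1 + 23400 / (PO2^3 + 150 * PO2)),   PO2 in mmHg.

Arterial oxygen content follows from haematocrit via [Hb] = Hct/3
(g/100 ml) and the carrying capacity of haemoglobin, 55.6 umol O2/g.
Dissolved oxygen is neglected (small in arteries, negligible in veins).

    OEF  = (SaO2 - SvO2) / SaO2
    CMRO2 = CBF * [O2]a * OEF      (umol O2 / 100 ml tissue / min)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientBreathsError

__all__ = [
    "RespiratoryTrace",
    "ArterialOxygen",
    "RegionalOxygenation",
    "end_tidal_values",
    "et_percent_to_po2",
    "severinghaus_sao2",
    "arterial_o2_content",
    "compute_oef",
    "compute_cmro2",
    "arterial_oxygen_from_trace",
    "O2_PER_GRAM_HB",
]

O2_PER_GRAM_HB = 55.6  # umol O2 per gram haemoglobin


@dataclass(frozen=True)
class RespiratoryTrace:
    """Sampled exhaled-O2 concentration, percent, with sampling rate in Hz."""

    samples: np.ndarray
    sampling_hz: float
    window: tuple[int, int] | None = None  # acquisition window, sample indices

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if np.any(samples < 0.0) or np.any(samples > 25.0):
            raise ValueError("O2 percentages must lie in [0, 25]")
        if self.sampling_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        object.__setattr__(self, "samples", samples)

    @property
    def windowed(self) -> np.ndarray:
        if self.window is None:
            return self.samples
        lo, hi = self.window
        if hi <= lo:
            raise ValueError("window is empty")
        return self.samples[lo:hi]

    @classmethod
    def from_csv(cls, path, sampling_hz: float | None = None) -> "RespiratoryTrace":
        """Read a (time_s, percent_o2) CSV; rate inferred from time column."""
        import pandas as pd

        df = pd.read_csv(path)
        t, y = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
        if sampling_hz is None:
            dt = np.median(np.diff(t))
            sampling_hz = 1.0 / dt
        return cls(samples=y, sampling_hz=float(sampling_hz))


@dataclass(frozen=True)
class ArterialOxygen:
    """Per-subject arterial oxygenation summary."""

    et_o2: float  # percent
    pet_o2: float  # mmHg
    sao2: float  # fraction
    hb: float  # g / 100 ml blood
    o2a: float  # umol O2 / 100 ml blood


@dataclass(frozen=True)
class RegionalOxygenation:
    territory: str
    oef: float
    cmro2: float  # umol O2 / 100 ml tissue / min


def end_tidal_values(trace: RespiratoryTrace, min_prominence: float = 0.5,
                     min_breath_interval_s: float = 1.5,
                     invert: bool = True):
    """End-tidal O2 values and their median, in percent.

    End-expiratory extrema are detected as peaks of the negated trace
    (minima of O2 concentration) with a minimum prominence (percent O2)
    and a minimum inter-breath spacing. ``invert=False`` finds raw maxima
    instead, for auditing against peak-picking on the un-negated trace.

    Returns ``(values, median)``; raises ``InsufficientBreathsError`` when
    fewer than 3 extrema are found.
    """
    y = trace.windowed
    distance = max(1, int(round(min_breath_interval_s * trace.sampling_hz)))
    signal = -y if invert else y
    peaks, _ = find_peaks(signal, prominence=min_prominence, distance=distance)
    if peaks.size < 3:
        raise InsufficientBreathsError(
            f"found {peaks.size} end-tidal extrema; need at least 3")
    values = y[peaks]
    return values, float(np.median(values))


def et_percent_to_po2(et_o2: float, barometric: float = 760.0,
                      water_vapour: float = 47.0) -> float:
    """Convert an end-tidal O2 fraction (percent) to partial pressure (mmHg).

    Alveolar gas is saturated with water vapour at body temperature, so the
    dry-gas fraction applies to ``barometric - water_vapour``.
    """
    if not 0.0 < et_o2 < 100.0:
        raise ValueError("end-tidal O2 percent must lie in (0, 100)")
    if barometric <= water_vapour:
        raise ValueError("barometric pressure must exceed water-vapour pressure")
    return et_o2 / 100.0 * (barometric - water_vapour)


def severinghaus_sao2(po2: float) -> float:
    """Haemoglobin O2 saturation (fraction) at a given PO2 (mmHg)."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 <= 0):
        raise ValueError("PO2 must be > 0")
    out = 1.0 / (1.0 + 23400.0 / (po2 ** 3 + 150.0 * po2))
    return float(out) if out.ndim == 0 else out


def arterial_o2_content(hct: float) -> float:
    """Arterial O2 content, umol O2 / 100 ml blood, from haematocrit.

    [Hb] in g/100 ml is estimated as Hct(%)/3; content is [Hb] * 55.6.
    """
    if not 0.0 < hct < 1.0:
        raise ValueError(f"haematocrit must lie in (0, 1), got {hct!r}")
    hb = hct * 100.0 / 3.0
    return hb * O2_PER_GRAM_HB


def compute_oef(sao2: float, svo2: float) -> float:
    """Oxygen extraction fraction (SaO2 - SvO2) / SaO2.

    Negative results (SvO2 above SaO2, possible under measurement noise)
    are returned unclamped with a ``UserWarning`` so that repeatability
    statistics see the full noise structure.
    """
    if sao2 <= 0.0 or sao2 > 1.0:
        raise ValueError("SaO2 must lie in (0, 1]")
    if not 0.0 <= svo2 <= 1.0:
        raise ValueError("SvO2 must lie in [0, 1]")
    oef = (sao2 - svo2) / sao2
    if oef < 0.0:
        warnings.warn("SvO2 exceeds SaO2: negative OEF returned unclamped",
                      UserWarning, stacklevel=2)
    return oef


def compute_cmro2(cbf: float, o2a: float, oef: float) -> float:
    """CMRO2 in umol O2 / 100 ml tissue / min.

    ``cbf`` in ml/100 ml/min, ``o2a`` in umol/100 ml blood; o2a/100
    converts the content to umol per ml of blood.
    """
    if cbf < 0 or o2a < 0:
        raise ValueError("CBF and arterial O2 content must be >= 0")
    return cbf * (o2a / 100.0) * oef


def arterial_oxygen_from_trace(trace: RespiratoryTrace, hct: float,
                               barometric: float = 760.0,
                               water_vapour: float = 47.0,
                               min_prominence: float = 0.5,
                               min_breath_interval_s: float = 1.5
                               ) -> ArterialOxygen:
    """End-tidal extraction through to arterial O2 content for one subject."""
    _, et = end_tidal_values(trace, min_prominence=min_prominence,
                             min_breath_interval_s=min_breath_interval_s)
    pet = et_percent_to_po2(et, barometric, water_vapour)
    sao2 = severinghaus_sao2(pet)
    hb = hct * 100.0 / 3.0
    return ArterialOxygen(et_o2=et, pet_o2=pet, sao2=sao2, hb=hb,
                          o2a=hb * O2_PER_GRAM_HB)
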