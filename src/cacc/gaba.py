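"""GABA reversal-potential analysis.

Evoked GABA-PSP amplitude depends linearly on membrane potential through the
driving force: amplitude = slope x (E_GABA - Em).  An ordinary least-squares
line through (Em, amplitude) pairs yields E_GABA as the zero-amplitude
intercept and DF_GABA = E_GABA - Em as the driving force at any holding
level.  Because the cell-attached configuration both attenuates amplitudes
(changing the slope, not the intercept) and offsets the apparent Em (shifting
the intercept), CA-frame estimates of E_GABA are biased; refitting the CA
amplitudes against the simultaneously measured WC membrane potential removes
that bias.  No Goldman-type rectification is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GabaFit:
    """Line fit of evoked amplitude vs membrane potential.

    ``slope`` is the amplitude change per mV of driving force (dimensionless
    conductance proxy, positive for a physical fit); ``E_GABA`` is the
    zero-amplitude intercept (mV; NaN when the slope vanishes).
    """

    slope: float
    E_GABA: float
    frame: str          # "WC" | "CA" | "CA-reframed-to-WC"
    r: float
    n_levels: int

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("a fit needs at least 2 levels")

    def driving_force_at(self, Em: float) -> float:
        return driving_force(self.E_GABA, Em)


def fit_amplitude_vs_em(amplitudes, em, frame: str = "WC") -> GabaFit:
    """OLS fit amplitude = slope x (E_GABA - Em).

    Requires at least two distinct Em levels.  With all-zero amplitudes the
    slope is 0 and E_GABA is NaN (undefined reversal).
    """
    amp = np.asarray(amplitudes, dtype=float)
    em = np.asarray(em, dtype=float)
    if amp.shape != em.shape or amp.ndim != 1:
        raise ValueError("amplitudes and em must be 1-D and the same length")
    if np.unique(em).size < 2:
        raise ValueError("need at least 2 distinct Em levels")
    # ordinary least squares: amplitude = a + b Em, slope = -b, E_GABA = -a/b
    res = stats.linregress(em, amp)
    slope = -res.slope
    if slope == 0 or not np.isfinite(slope):
        return GabaFit(slope=0.0, E_GABA=float("nan"), frame=frame,
                       r=float(res.rvalue), n_levels=int(np.unique(em).size))
    e_gaba = res.intercept / slope
    return GabaFit(slope=float(slope), E_GABA=float(e_gaba), frame=frame,
                   r=float(res.rvalue), n_levels=int(np.unique(em).size))


def driving_force(E_GABA: float, Em: float) -> float:
    """GABA driving force DF = E_GABA - Em (mV)."""
    if not (np.isfinite(E_GABA) and np.isfinite(Em)):
        raise ValueError("E_GABA and Em must be finite")
    return E_GABA - Em


def reframe_ca_to_wc(ca_amplitudes, em_wc_levels) -> GabaFit:
    """Fit CA amplitudes against the simultaneous WC membrane potential.

    The seal-induced offset between the CA and WC voltage scales shifts the
    native CA-frame reversal estimate; expressing the same CA amplitudes as
    a function of Em measured in WC removes the offset, while the amplitude
    attenuation only rescales the slope (the x-intercept is invariant to
    scaling all amplitudes by a positive constant).
    """
    ca = np.asarray(ca_amplitudes, dtype=float)
    em = np.asarray(em_wc_levels, dtype=float)
    if ca.shape != em.shape:
        raise ValueError("CA amplitudes must be paired with WC Em levels")
    return fit_amplitude_vs_em(ca, em, frame="CA-reframed-to-WC")


def classify_polarity(evoked_amplitude_mv: float, isoelectric_band: float = 0.3) -> str:
    """Label a response depolarizing / hyperpolarizing / isoelectric.

    ``isoelectric_band`` (mV) is a dead band around zero, roughly the noise
    floor of averaged evoked traces.
    """
    if abs(evoked_amplitude_mv) <= isoelectric_band:
        return "isoelectric"
    return "depolarizing" if evoked_amplitude_mv > 0 else "hyperpolarizing"
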