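"""Ionoluminescence photophysics: relative yield and emission lifetime.

Relative yield
--------------
The absolute ionoluminescence quantum yield of a nanoparticle cannot be
measured directly (it folds in collection geometry, beam current and energy
deposition), so yields are expressed relative to a reference scintillator
imaged with the same collection geometry.  For one acquisition the raw
yield is the number of IL photons divided by (number of incident ions x
their mean energy loss); the relative yield is the ratio of sample to
reference raw yields, so the reference is unity by construction.

Lifetime
--------
Time-correlated single-photon counting histograms (50 ps bins by default)
are fitted by iterative reconvolution: the model is an amplitude times the
discrete convolution of the measured instrument response function (IRF)
with a single-exponential decay exp(-t/tau), plus a constant background,
least-squares fitted to the binned counts.  When no IRF is available a
tail-only pure-exponential fit is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

# Planck constant x speed of light, in eV nm (CODATA)
HC_EV_NM = 1239.841984


def bandgap_emission_wavelength_nm(gap_ev: float) -> float:
    """Photon wavelength (nm) of a band-to-band emission of energy ``gap_ev``.

    Diamond's indirect gap of ~5.47 eV corresponds to ~227 nm.
    """
    if gap_ev <= 0:
        raise ValueError("gap energy must be positive")
    return HC_EV_NM / gap_ev


@dataclass
class DecayHistogram:
    """Time-binned photon arrivals with the instrument response on the same grid."""

    bin_width_ps: float
    counts: np.ndarray
    irf: np.ndarray | None = None  # unit-area instrument response, same grid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_width_ps <= 0:
            raise ValueError("bin width must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.irf is not None:
            self.irf = np.asarray(self.irf, dtype=float)
            if self.irf.shape != self.counts.shape:
                raise ValueError("IRF must share the histogram grid")
            s = self.irf.sum()
            if s <= 0:
                raise ValueError("IRF must have positive mass")
            self.irf = self.irf / s

    @property
    def t_ns(self) -> np.ndarray:
        """Bin centers in ns."""
        return (np.arange(self.counts.size) + 0.5) * self.bin_width_ps * 1e-3

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass
class YieldRecord:
    il_counts: float
    ion_counts: float
    mean_de_kev: float
    raw_yield: float
    relative_yield: float


def _raw_yield(events) -> tuple[float, float, float]:
    """Total IL photons, ion count and mean dE of one list-mode acquisition."""
    df = events.records
    il = float(df.loc[df["channel"] == "IL", "value"].sum())
    stim = df.loc[df["channel"] == "STIM", "value"]
    n_ion = float(len(stim))
    if n_ion == 0:
        raise ValueError("acquisition has no transmitted-ion (STIM) events")
    mean_de = float(stim.mean())
    if mean_de <= 0:
        raise ValueError("mean energy loss must be positive")
    return il, n_ion, mean_de


def relative_yield(sample, reference) -> YieldRecord:
    """Relative IL yield of ``sample`` against ``reference`` (both EventLists).

    raw = sum(IL) / (n_ions * mean dE); relative = raw_sample / raw_reference.
    """
    il_s, n_s, de_s = _raw_yield(sample)
    il_r, n_r, de_r = _raw_yield(reference)
    raw_s = il_s / (n_s * de_s)
    raw_r = il_r / (n_r * de_r)
    if raw_r <= 0:
        raise ValueError("reference yield is zero")
    return YieldRecord(il_counts=il_s, ion_counts=n_s, mean_de_kev=de_s,
                       raw_yield=raw_s, relative_yield=raw_s / raw_r)


# ---------------------------------------------------------------------------
# lifetime fitting
# ---------------------------------------------------------------------------

def _reconvolved_model(t_ns, irf, tau, amplitude, background):
    decay = np.exp(-t_ns / tau)
    conv = np.convolve(irf, decay)[: t_ns.size]
    return amplitude * conv + background


def _tail_tau_guess(t_ns, counts) -> float:
    # log-linear fit over the decaying tail (from the peak onward)
    i0 = int(np.argmax(counts))
    t, c = t_ns[i0:], counts[i0:]
    good = c > max(1.0, 0.001 * counts.max())
    if good.sum() < 5:
        return max(t_ns[-1] / 5.0, t_ns[1] - t_ns[0])
    slope = np.polyfit(t[good], np.log(c[good]), 1)[0]
    return -1.0 / slope if slope < 0 else t_ns[-1] / 5.0


def fit_lifetime(hist: DecayHistogram) -> dict:
    """Fit the emission lifetime tau (ns) of a decay histogram.

    Reconvolution fit when the histogram carries an IRF, tail fit otherwise.

    Returns
    -------
    dict with ``tau_ns``, ``tau_se_ns``, ``amplitude``, ``background``,
    ``method`` and an ``at_bound`` flag.
    """
    if hist.total_counts < 100:
        raise ValueError("need at least 100 photons to fit a lifetime")
    t = hist.t_ns
    c = hist.counts
    tau0 = _tail_tau_guess(t, c)
    t_span = t[-1]
    bounds = ([t[1] - t[0], 0.0, 0.0], [10.0 * t_span, np.inf, np.inf])

    if hist.irf is not None:
        def model(tt, tau, amp, bg):
            return _reconvolved_model(tt, hist.irf, tau, amp, bg)
        method = "reconvolution"
    else:
        i0 = int(np.argmax(c))
        t, c = t[i0:], c[i0:]
        t0 = t[0]

        def model(tt, tau, amp, bg):
            return amp * np.exp(-(tt - t0) / tau) + bg
        method = "tail"

    amp0 = float(c.max())
    # unweighted least squares: empirical sqrt(N) weights bias tau low in
    # sparsely filled tail bins, and counts are large in this regime anyway
    try:
        popt, pcov = optimize.curve_fit(
            model, t, c, p0=[tau0, amp0, 0.0],
            bounds=bounds, maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"lifetime fit did not converge: {exc}") from None
    tau, amp, bg = popt
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    at_bound = bool(np.isclose(tau, bounds[0][0]) or np.isclose(tau, bounds[1][0]))
    return {"tau_ns": float(tau), "tau_se_ns": se, "amplitude": float(amp),
            "background": float(bg), "method": method, "at_bound": at_bound}
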