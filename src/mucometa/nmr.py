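"""1H NMR spectral preprocessing.

Turns per-sample (ppm, intensity) spectra into the statistical matrix used
for multivariate modelling: chemical-shift calibration on the alanine methyl
doublet (1.47 ppm), binning of the -1..10 ppm region at 0.00055 ppm
resolution, exclusion of solvent/contaminant regions (water, ethanol,
polyethylene glycol), probabilistic quotient normalization (PQN) and unit
variance scaling.  STOCSY (statistical total correlation spectroscopy) is
provided for data-driven peak assignment.

The stages must run in order: calibrate -> bin -> exclude -> normalize ->
scale.  The matrix tracks its processing state and raises
:class:`PipelineStateError` when a stage is applied out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Spectrum",
    "SpectralMatrix",
    "ExclusionRegion",
    "DEFAULT_EXCLUSIONS",
    "ALANINE_CH3_PPM",
    "calibrate_to_alanine",
    "bin_spectra",
    "apply_exclusions",
    "pqn_normalize",
    "unit_variance_scale",
    "stocsy",
]

ALANINE_CH3_PPM = 1.47

BIN_LO, BIN_HI, BIN_RESOLUTION = -1.0, 10.0, 0.00055


class PipelineStateError(RuntimeError):
    """A preprocessing stage was applied out of order."""


class CalibrationError(ValueError):
    """No usable calibration peak in the search window."""


@dataclass
class Spectrum:
    """A single 1D spectrum: strictly monotone ppm axis + intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError(f"{self.sample_id}: ppm/intensity length mismatch")
        d = np.diff(self.ppm)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError(f"{self.sample_id}: ppm axis must be strictly monotone")

    def ascending(self) -> "Spectrum":
        if self.ppm[0] > self.ppm[-1]:
            return replace(self, ppm=self.ppm[::-1].copy(), intensity=self.intensity[::-1].copy())
        return self


@dataclass
class ExclusionRegion:
    lo_ppm: float
    hi_ppm: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lo_ppm < self.hi_ppm:
            raise ValueError(f"exclusion region {self.label!r}: lo must be < hi")

    def contains(self, ppm: np.ndarray) -> np.ndarray:
        return (ppm >= self.lo_ppm) & (ppm <= self.hi_ppm)


#: solvent and contaminant windows removed before modelling
DEFAULT_EXCLUSIONS = (
    ExclusionRegion(4.50, 5.19, "water"),
    ExclusionRegion(1.10, 1.20, "ethanol CH3"),
    ExclusionRegion(3.60, 3.90, "ethanol CH2"),
    ExclusionRegion(3.70, 3.75, "polyethylene glycol"),
)


@dataclass
class SpectralMatrix:
    """Samples x ppm-bins intensity matrix with processing provenance.

    ``flags`` record which stages have run; ``dilution_factors`` are filled
    by PQN; ``zero_variance_columns`` are flagged (not dropped) by unit
    variance scaling so that bin indices stay stable.
    """

    bins: np.ndarray
    X: np.ndarray
    sample_ids: list[str]
    flags: dict = field(
        default_factory=lambda: {
            "calibrated": False,
            "excluded": False,
            "normalized": False,
            "scaled": False,
        }
    )
    dilution_factors: np.ndarray | None = None
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    zero_variance_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.sample_ids), self.bins.size):
            raise ValueError("matrix shape inconsistent with sample_ids/bins")
        if not (np.diff(self.bins) > 0).all():
            raise ValueError("bin centres must be strictly increasing")
        if not np.isfinite(self.X).all():
            raise ValueError("matrix contains non-finite values")

    def bin_index(self, ppm: float) -> int:
        """Index of the bin whose centre is nearest to ``ppm``."""
        return int(np.argmin(np.abs(self.bins - ppm)))


# -------------------------------------------------------------- calibration


def calibrate_to_alanine(
    s: Spectrum,
    search_window: tuple[float, float] = (1.40, 1.54),
    target_ppm: float = ALANINE_CH3_PPM,
) -> Spectrum:
    """Shift the ppm axis so the tallest peak in the window sits at 1.47 ppm.

    The apex is the tallest local maximum inside ``search_window``; a flat
    window has no calibration peak and raises.  When several local maxima are
    within 10% of the tallest (the two lines of the alanine doublet), the
    lowest-ppm one is used — a fixed convention, so every spectrum of a
    cohort is referenced to the same line and stays mutually aligned.
    """
    s = s.ascending()
    lo, hi = search_window
    if lo < s.ppm[0] or hi > s.ppm[-1]:
        raise CalibrationError(
            f"{s.sample_id}: search window {search_window} outside spectral axis"
        )
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise CalibrationError(f"{s.sample_id}: too few points in search window")
    win = s.intensity[idx]
    if np.isclose(win.max(), win.min()):
        raise CalibrationError(f"{s.sample_id}: flat search window, no peak to calibrate")
    interior = np.arange(1, idx.size - 1)
    is_max = (win[interior] >= win[interior - 1]) & (win[interior] >= win[interior + 1])
    peaks = interior[is_max]
    if peaks.size == 0:
        raise CalibrationError(f"{s.sample_id}: no local maximum in search window")
    tall = peaks[win[peaks] >= 0.9 * win[peaks].max()]
    apex = idx[tall[0]]
    shift = target_ppm - s.ppm[apex]
    return replace(s, ppm=s.ppm + shift, calibrated=True)


# ------------------------------------------------------------------ binning


def bin_spectra(
    spectra: list[Spectrum],
    lo: float = BIN_LO,
    hi: float = BIN_HI,
    resolution: float = BIN_RESOLUTION,
    require_calibrated: bool = True,
) -> SpectralMatrix:
    """Bin spectra onto a common axis of half-open intervals [lo+k*res, lo+(k+1)*res).

    The bin value is the mean intensity of the raw points falling in the bin
    (0 when a bin receives no points).  Defaults give 20000 bins over
    -1..10 ppm.
    """
    if not spectra:
        raise ValueError("empty spectrum list")
    if require_calibrated:
        bad = [s.sample_id for s in spectra if not s.calibrated]
        if bad:
            raise PipelineStateError(f"spectra not calibrated before binning: {bad}")
    n_bins = int(round((hi - lo) / resolution))
    if n_bins < 1:
        raise ValueError("resolution larger than the binning range")
    centres = lo + (np.arange(n_bins) + 0.5) * resolution
    X = np.zeros((len(spectra), n_bins))
    for i, s in enumerate(spectra):
        s = s.ascending()
        k = np.floor((s.ppm - lo) / resolution).astype(np.int64)
        ok = (k >= 0) & (k < n_bins)
        sums = np.bincount(k[ok], weights=s.intensity[ok], minlength=n_bins)
        counts = np.bincount(k[ok], minlength=n_bins)
        nz = counts > 0
        X[i, nz] = sums[nz] / counts[nz]
    return SpectralMatrix(
        bins=centres,
        X=X,
        sample_ids=[s.sample_id for s in spectra],
        flags={"calibrated": all(s.calibrated for s in spectra),
               "excluded": False, "normalized": False, "scaled": False},
    )


# --------------------------------------------------------------- exclusions


def apply_exclusions(
    m: SpectralMatrix, regions: tuple[ExclusionRegion, ...] = DEFAULT_EXCLUSIONS
) -> SpectralMatrix:
    """Remove columns whose bin centre falls inside any exclusion region."""
    if m.flags["normalized"] or m.flags["scaled"]:
        raise PipelineStateError("exclusions must be applied before normalization")
    drop = np.zeros(m.bins.size, dtype=bool)
    for region in regions:
        drop |= region.contains(m.bins)
    if drop.all():
        raise ValueError("exclusion regions cover the entire spectral axis")
    keep = ~drop
    return SpectralMatrix(
        bins=m.bins[keep],
        X=m.X[:, keep],
        sample_ids=list(m.sample_ids),
        flags={**m.flags, "excluded": True},
    )


# ---------------------------------------------------------------------- PQN


def pqn_normalize(m: SpectralMatrix) -> SpectralMatrix:
    """Probabilistic quotient normalization against the median spectrum.

    (1) each row is total-area normalized; (2) the reference is the
    column-wise median of the area-normalized rows; (3) each row's quotient
    factor is the median of row/reference over columns where the reference is
    positive; (4) the row is divided by its factor.  The stored per-sample
    dilution factor is area x quotient, i.e. the total scale removed from the
    raw row — proportional to the physical dilution.
    """
    if not m.flags["excluded"]:
        raise PipelineStateError("apply exclusions before PQN")
    if m.flags["scaled"]:
        raise PipelineStateError("cannot normalize after scaling")
    X = m.X.copy()
    areas = X.sum(axis=1)
    if (areas <= 0).any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(areas <= 0)]
        raise ValueError(f"zero or negative total area for samples {bad}")
    X = X / areas[:, None]
    reference = np.median(X, axis=0)
    if (reference <= 0).all():
        raise ValueError("all-zero reference spectrum")
    pos = reference > 0
    quotients = np.median(X[:, pos] / reference[pos], axis=1)
    if (quotients <= 0).any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(quotients <= 0)]
        raise ValueError(f"nonpositive quotient factor for samples {bad}")
    X = X / quotients[:, None]
    return SpectralMatrix(
        bins=m.bins.copy(),
        X=X,
        sample_ids=list(m.sample_ids),
        flags={**m.flags, "normalized": True},
        dilution_factors=areas * quotients,
    )


# -------------------------------------------------------------- UV scaling


def unit_variance_scale(m: SpectralMatrix) -> SpectralMatrix:
    """Mean-centre each column and divide by its sample standard deviation.

    Zero-variance columns are centred only and flagged in
    ``zero_variance_columns`` so model stages can ignore them without
    disturbing bin indexing.
    """
    if not m.flags["normalized"]:
        raise PipelineStateError("normalize (PQN) before unit variance scaling")
    if m.flags["scaled"]:
        raise PipelineStateError("matrix already scaled")
    means = m.X.mean(axis=0)
    sds = m.X.std(axis=0, ddof=1) if m.X.shape[0] > 1 else np.zeros(m.X.shape[1])
    zero_var = sds <= 0
    safe = np.where(zero_var, 1.0, sds)
    X = (m.X - means) / safe
    return SpectralMatrix(
        bins=m.bins.copy(),
        X=X,
        sample_ids=list(m.sample_ids),
        flags={**m.flags, "scaled": True},
        dilution_factors=None if m.dilution_factors is None else m.dilution_factors.copy(),
        column_means=means,
        column_sds=sds,
        zero_variance_columns=zero_var,
    )


# ------------------------------------------------------------------- STOCSY


def stocsy(m: SpectralMatrix, driver_ppm: float) -> tuple[np.ndarray, np.ndarray]:
    """Correlate every bin against the driver bin for structural assignment.

    Returns per-bin (Pearson r, covariance) against the column nearest to
    ``driver_ppm``.  Peaks of the same molecule share a concentration and so
    correlate near 1; independently varying molecules do not.  Computed on
    the PQN-normalized (never UV-scaled) matrix.
    """
    if m.flags["scaled"]:
        raise PipelineStateError("STOCSY must run on the normalized, unscaled matrix")
    if m.X.shape[0] < 3:
        raise ValueError("STOCSY needs at least 3 samples")
    j = m.bin_index(driver_ppm)
    driver = m.X[:, j]
    if np.isclose(driver.std(), 0.0):
        raise ValueError(f"driver column at {m.bins[j]:.4f} ppm is constant")
    Xc = m.X - m.X.mean(axis=0)
    d = driver - driver.mean()
    n = m.X.shape[0]
    cov = Xc.T @ d / (n - 1)
    sds = Xc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / (sds * d.std(ddof=1))
    r[~np.isfinite(r)] = 0.0
    return r, cov
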