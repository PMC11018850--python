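"""Raw spectra → aligned, filtered, standardized fingerprint matrix.

The processing chain mirrors common MALDI-TOF practice: baseline correction
(morphological opening), Savitzky–Golay smoothing, local-maximum peak picking
against a robust sliding-window noise estimate (S/N ≥ 3 by default), greedy
ppm-tolerance alignment of peaks across samples, a ≥ 2/3 within-group presence
filter, and z-score standardization learned on a training subset only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.signal

from . import io_mzml
from .exceptions import DataError, ParameterError, SpectrumParseError
from .utils import EC, NON_EC

__all__ = [
    "Spectrum",
    "Peak",
    "PeakList",
    "AlignedFeature",
    "StandardizationParams",
    "FeatureMatrix",
    "read_spectrum",
    "write_spectrum",
    "correct_baseline",
    "smooth",
    "detect_peaks",
    "align_peaks",
    "filter_features",
    "build_matrix",
    "standardize",
    "apply_standardization",
    "inverse_standardize",
    "preprocess_cohort",
]


@dataclass
class Spectrum:
    """One sample's profile spectrum: strictly increasing m/z (Da), intensity ≥ 0."""

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    group: str = "unknown"

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise DataError(f"{self.sample_id}: mz and intensity lengths differ")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise DataError(f"{self.sample_id}: mz not strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise DataError(f"{self.sample_id}: non-finite intensities")
        if np.any(self.intensity < 0):
            raise DataError(f"{self.sample_id}: negative intensities")

    def __len__(self) -> int:
        return self.mz.size


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: float


@dataclass
class PeakList:
    """Peaks detected in one spectrum, sorted by m/z, each with its S/N."""

    sample_id: str
    peaks: list[Peak]
    group: str = "unknown"

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


@dataclass
class AlignedFeature:
    """One consensus m/z feature with per-sample member intensities."""

    consensus_mz: float
    member_peaks: dict[str, float]
    presence_fraction_by_group: dict[str, float] = field(default_factory=dict)


@dataclass
class StandardizationParams:
    """Per-feature (mean, sd) learned on a training subset; sd uses ddof=0."""

    mean: np.ndarray
    sd: np.ndarray
    feature_mzs: np.ndarray


@dataclass
class FeatureMatrix:
    """Samples × aligned m/z features — the fingerprint (SMF) container.

    ``values`` is dense (missing entries already imputed).  When standardized,
    ``standardization`` carries the training-set parameters for reuse on
    held-out data.
    """

    sample_ids: list[str]
    groups: np.ndarray
    feature_mzs: np.ndarray
    values: np.ndarray
    standardization: StandardizationParams | None = None
    normalized: bool = False

    def __post_init__(self):
        self.groups = np.asarray(self.groups)
        self.feature_mzs = np.asarray(self.feature_mzs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.sample_ids) != n or self.groups.size != n:
            raise DataError("sample_ids/groups length does not match matrix rows")
        if self.feature_mzs.size != p:
            raise DataError("feature_mzs length does not match matrix columns")
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample_ids in matrix")
        if np.isnan(self.values).any():
            raise DataError("matrix contains missing values after imputation")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def row_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids])
        except KeyError as exc:
            raise DataError(f"unknown sample_id {exc.args[0]!r}") from exc

    def subset(self, sample_ids) -> "FeatureMatrix":
        idx = self.row_index(sample_ids)
        return FeatureMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            groups=self.groups[idx],
            feature_mzs=self.feature_mzs.copy(),
            values=self.values[idx].copy(),
            standardization=self.standardization,
            normalized=self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{mz:.4f}" for mz in self.feature_mzs],
        )
        df.insert(0, "group", self.groups)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)
        if self.standardization is not None:
            side = pd.DataFrame(
                {
                    "feature_mz": self.standardization.feature_mzs,
                    "mean": self.standardization.mean,
                    "sd": self.standardization.sd,
                }
            )
            side.to_csv(str(path) + ".standardization.csv", index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        groups = df.pop("group").to_numpy()
        return cls(
            sample_ids=[str(s) for s in df.index],
            groups=groups,
            feature_mzs=np.array([float(c) for c in df.columns]),
            values=df.to_numpy(dtype=float),
        )


# ---------------------------------------------------------------- I/O


def read_spectrum(path, dialect: str = "tsv", sample_id: str | None = None,
                  group: str = "unknown") -> Spectrum:
    """Read one spectrum from a two-column (m/z, intensity) text file or mzML.

    Rows are sorted by m/z; duplicate m/z values are merged by intensity sum.
    """
    if sample_id is None:
        name = str(path).rsplit("/", 1)[-1]
        sample_id = name.rsplit(".", 1)[0]
    if dialect == "tsv":
        mzs, intens = [], []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", "\t").split()
                if len(parts) < 2:
                    raise SpectrumParseError(f"{path}:{lineno}: expected two columns")
                try:
                    mzs.append(float(parts[0]))
                    intens.append(float(parts[1]))
                except ValueError as exc:
                    raise SpectrumParseError(
                        f"{path}:{lineno}: non-numeric value {parts[:2]}"
                    ) from exc
        mz = np.array(mzs)
        intensity = np.array(intens)
    elif dialect == "mzml":
        mz, intensity = io_mzml.read_mzml(path)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    if uniq.size != mz.size:  # merge duplicate m/z by summing intensity
        intensity = np.bincount(inverse, weights=intensity)
        mz = uniq
    return Spectrum(sample_id=sample_id, mz=mz, intensity=np.clip(intensity, 0, None),
                    group=group)


def write_spectrum(s: Spectrum, path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        np.savetxt(path, np.column_stack([s.mz, s.intensity]),
                   fmt="%.6f\t%.6f", delimiter="\t")
    elif dialect == "mzml":
        io_mzml.write_mzml(path, s.mz, s.intensity, run_id=s.sample_id)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------- signal chain


def correct_baseline(s: Spectrum, half_window: int = 50) -> Spectrum:
    """Subtract a morphological (rolling-minimum/opening) baseline estimate.

    The opening (erosion then dilation with a flat structuring element of
    2·half_window+1 points) tracks any smooth baseline while ignoring peaks
    narrower than the window; the estimate is lightly smoothed to avoid
    staircase artifacts.  Output is clipped at 0.
    """
    if half_window < 1:
        raise ParameterError("half_window must be ≥ 1")
    if len(s) and half_window >= len(s):
        raise ParameterError("half_window must be smaller than the spectrum length")
    if len(s) == 0:
        return s
    size = 2 * half_window + 1
    baseline = ndi.grey_opening(s.intensity, size=size, mode="nearest")
    baseline = ndi.uniform_filter1d(baseline, size=size, mode="nearest")
    corrected = np.clip(s.intensity - baseline, 0.0, None)
    return replace(s, intensity=corrected)


def smooth(s: Spectrum, window: int = 9, polyorder: int = 3) -> Spectrum:
    """Savitzky–Golay smoothing (peak-shape preserving)."""
    if window % 2 == 0:
        raise ParameterError("window must be odd")
    if polyorder >= window:
        raise ParameterError("polyorder must be smaller than window")
    if len(s) < window:
        return s
    sm = scipy.signal.savgol_filter(s.intensity, window_length=window,
                                    polyorder=polyorder)
    return replace(s, intensity=np.clip(sm, 0.0, None))


def _blockwise(y: np.ndarray, window: int, stat) -> np.ndarray:
    """Apply ``stat`` per non-overlapping block, interpolate to the grid."""
    n = y.size
    window = max(min(window, n), 8)
    n_blocks = max(n // window, 1)
    edges = np.linspace(0, n, n_blocks + 1, dtype=int)
    centers = (edges[:-1] + edges[1:]) / 2.0
    vals = np.array([stat(y[edges[b]:edges[b + 1]]) for b in range(n_blocks)])
    return np.interp(np.arange(n), centers, vals)


def _local_level(y: np.ndarray, window: int) -> np.ndarray:
    """Blockwise local median, interpolated (robust background level)."""
    return _blockwise(y, window, np.median)


def _local_noise(y: np.ndarray, window: int) -> np.ndarray:
    """Blockwise robust noise sd of a spectrum containing peaks.

    Works on the high-pass residual of a short Savitzky–Golay fit, where
    smooth structure (baseline remnants and all but the sharpest peak
    curvature) cancels, and measures its upper-quartile spread
    (q75 − q50)/0.6745 — which stays unbiased when the lower noise half has
    been clipped at zero, because clipping and any locally smooth shift move
    both quartiles together.  The known white-noise attenuation of the
    high-pass filter is divided back out.
    """
    w, p = 9, 3
    if y.size <= w:
        q50, q75 = np.percentile(y, [50.0, 75.0])
        return np.full(y.size, (q75 - q50) / 0.6745)
    resid = y - scipy.signal.savgol_filter(y, w, p)
    h = scipy.signal.savgol_coeffs(w, p)
    h0 = h[w // 2]
    kappa = np.sqrt(1.0 - 2.0 * h0 + np.sum(h**2))  # sd of residual white noise

    def spread(block):
        q50, q75 = np.percentile(block, [50.0, 75.0])
        return (q75 - q50) / 0.6745

    return _blockwise(resid, window, spread) / kappa


def detect_peaks(s: Spectrum, snr_threshold: float = 3.0,
                 noise_window: int = 501,
                 noise_reference: "Spectrum | None" = None) -> PeakList:
    """Pick local maxima with S/N ≥ ``snr_threshold``.

    S/N is the apex height above the local median, divided by a
    sliding-window MAD noise estimate (robust to the peaks themselves).
    Expects a baseline-corrected, smoothed spectrum.  Smoothing shrinks the
    apparent noise, so when ``noise_reference`` (normally the
    baseline-corrected spectrum *before* smoothing) is given, the noise
    scale is estimated from it instead, keeping the S/N threshold anchored
    to the raw noise level.  An empty spectrum yields an empty PeakList.
    """
    if len(s) == 0 or not np.any(s.intensity > 0):
        return PeakList(sample_id=s.sample_id, peaks=[], group=s.group)
    ref = s.intensity if noise_reference is None else noise_reference.intensity
    if ref.shape != s.intensity.shape:
        raise ParameterError("noise_reference length differs from spectrum")
    noise = _local_noise(ref, noise_window)
    floor = max(float(np.median(noise)), 1e-12)
    noise = np.maximum(noise, floor * 1e-3)
    center = _local_level(s.intensity, noise_window)
    idx, _ = scipy.signal.find_peaks(s.intensity, height=0.0)
    peaks = []
    for i in idx:
        snr = (s.intensity[i] - center[i]) / noise[i]
        if snr >= snr_threshold:
            mz, apex = _refine_apex(s.mz, s.intensity, i)
            peaks.append(Peak(mz=mz, intensity=apex, snr=float(snr)))
    return PeakList(sample_id=s.sample_id, peaks=peaks, group=s.group)


def _refine_apex(mz: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid apex position/height by a 3-point parabola around index i.

    Removes the ±half-grid-step quantization that would otherwise dominate
    the ppm error of peak positions at low m/z.
    """
    if i == 0 or i == y.size - 1:
        return float(mz[i]), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # not locally concave; keep the grid point
        return float(mz[i]), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = mz[i + 1] - mz[i] if delta >= 0 else mz[i] - mz[i - 1]
    apex = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return float(mz[i] + delta * step), float(apex)


# ---------------------------------------------------------------- alignment


def align_peaks(peaklists: list[PeakList], tolerance_ppm: float = 300.0
                ) -> list[AlignedFeature]:
    """Greedy single-linkage clustering of pooled peaks along m/z.

    Peaks from all samples are pooled and sorted; a feature grows while the
    next peak lies within ``tolerance_ppm`` of the running intensity-weighted
    consensus m/z.  Each input peak joins at most one feature; if one sample
    contributes several peaks to a feature the most intense is kept.
    """
    if tolerance_ppm <= 0:
        raise ParameterError("tolerance_ppm must be > 0")
    if len(peaklists) < 2:
        raise ParameterError("alignment needs at least 2 peak lists")

    pooled = []
    for pl in peaklists:
        for p in pl.peaks:
            pooled.append((p.mz, p.intensity, pl.sample_id))
    pooled.sort(key=lambda t: t[0])

    features: list[AlignedFeature] = []
    cur: list[tuple[float, float, str]] = []
    cur_wsum = cur_w = 0.0

    def close():
        if not cur:
            return
        consensus = cur_wsum / cur_w
        members: dict[str, float] = {}
        for mz, inten, sid in cur:
            if sid not in members or inten > members[sid]:
                members[sid] = inten
        features.append(AlignedFeature(consensus_mz=consensus, member_peaks=members))

    for mz, inten, sid in pooled:
        w = max(inten, 1e-12)
        if cur:
            consensus = cur_wsum / cur_w
            if (mz - consensus) > consensus * tolerance_ppm * 1e-6:
                close()
                cur, cur_wsum, cur_w = [], 0.0, 0.0
        cur.append((mz, inten, sid))
        cur_wsum += w * mz
        cur_w += w
    close()
    return features


def filter_features(features: list[AlignedFeature], manifest: pd.DataFrame,
                    min_fraction: float = 2.0 / 3.0) -> list[AlignedFeature]:
    """Retain features present in ≥ ``min_fraction`` of at least one group.

    Presence fractions are computed against the manifest group sizes (not the
    number of samples that happened to yield the peak); the boundary is
    inclusive.  Group labels must be EC / NonEC.
    """
    group_of = dict(zip(manifest["sample_id"].astype(str), manifest["group"]))
    valid = {EC, NON_EC}
    bad = set(group_of.values()) - valid
    if bad:
        raise DataError(f"unknown group label(s) {sorted(bad)}; expected {sorted(valid)}")
    sizes = manifest["group"].value_counts().to_dict()

    kept = []
    for feat in features:
        counts: dict[str, int] = {g: 0 for g in sizes}
        for sid in feat.member_peaks:
            if sid not in group_of:
                raise DataError(f"sample {sid!r} not in manifest")
            counts[group_of[sid]] += 1
        fractions = {g: counts[g] / sizes[g] for g in sizes}
        feat.presence_fraction_by_group = fractions
        if any(frac >= min_fraction for frac in fractions.values()):
            kept.append(feat)
    return kept


def build_matrix(features: list[AlignedFeature], manifest: pd.DataFrame,
                 impute: str = "zero", normalize: str = "none") -> FeatureMatrix:
    """Assemble the dense samples × features matrix from aligned features.

    Missing entries are imputed (``zero`` or ``half_min`` of the feature's
    detected minimum); with ``normalize='tic'`` each row is first divided by
    its total detected intensity.
    """
    sample_ids = [str(s) for s in manifest["sample_id"]]
    if len(set(sample_ids)) != len(sample_ids):
        raise DataError("duplicate sample_ids in manifest")
    if impute not in {"zero", "half_min"}:
        raise ParameterError(f"unknown impute policy {impute!r}")
    if normalize not in {"none", "tic"}:
        raise ParameterError(f"unknown normalize policy {normalize!r}")

    order = np.argsort([f.consensus_mz for f in features], kind="stable")
    features = [features[i] for i in order]
    n, p = len(sample_ids), len(features)
    values = np.full((n, p), np.nan)
    row = {sid: i for i, sid in enumerate(sample_ids)}
    for j, feat in enumerate(features):
        for sid, inten in feat.member_peaks.items():
            if sid in row:
                values[row[sid], j] = inten

    if normalize == "tic":
        totals = np.nansum(values, axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        values = values / totals

    if impute == "zero":
        values = np.nan_to_num(values, nan=0.0)
    else:
        for j in range(p):
            col = values[:, j]
            detected = col[~np.isnan(col)]
            fill = detected.min() / 2.0 if detected.size else 0.0
            col[np.isnan(col)] = fill

    return FeatureMatrix(
        sample_ids=sample_ids,
        groups=manifest["group"].to_numpy(),
        feature_mzs=np.array([f.consensus_mz for f in features]),
        values=values,
        normalized=(normalize == "tic"),
    )


# ---------------------------------------------------------------- standardization


def fit_standardization(values: np.ndarray, feature_mzs: np.ndarray
                        ) -> tuple[StandardizationParams, np.ndarray]:
    """Compute per-feature (mean, sd) and the mask of usable (sd > 0) features."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = feature_mzs[~keep]
        warnings.warn(
            f"dropping {dropped.size} zero-variance feature(s): "
            f"{[f'{m:.4f}' for m in dropped[:5]]}...",
            stacklevel=2,
        )
    params = StandardizationParams(mean=mean[keep], sd=sd[keep],
                                   feature_mzs=feature_mzs[keep])
    return params, keep


def standardize(m: FeatureMatrix, train_ids: list[str] | None = None
                ) -> FeatureMatrix:
    """Z-score all rows with mean/sd learned on ``train_ids`` (default: all).

    Zero-variance features (on the training subset) are dropped with a
    warning.  The learned parameters are stored on the result for held-out
    reuse.
    """
    train_ids = list(train_ids) if train_ids is not None else list(m.sample_ids)
    idx = m.row_index(train_ids)
    params, keep = fit_standardization(m.values[idx], m.feature_mzs)
    z = (m.values[:, keep] - params.mean) / params.sd
    return FeatureMatrix(
        sample_ids=list(m.sample_ids),
        groups=m.groups.copy(),
        feature_mzs=params.feature_mzs.copy(),
        values=z,
        standardization=params,
        normalized=m.normalized,
    )


def apply_standardization(m: FeatureMatrix, params: StandardizationParams
                          ) -> FeatureMatrix:
    """Apply previously learned z-scoring parameters to (held-out) rows."""
    pos = {round(mz, 9): j for j, mz in enumerate(m.feature_mzs)}
    try:
        cols = np.array([pos[round(mz, 9)] for mz in params.feature_mzs])
    except KeyError as exc:
        raise DataError(f"feature {exc.args[0]} missing from matrix") from exc
    z = (m.values[:, cols] - params.mean) / params.sd
    return FeatureMatrix(
        sample_ids=list(m.sample_ids),
        groups=m.groups.copy(),
        feature_mzs=params.feature_mzs.copy(),
        values=z,
        standardization=params,
        normalized=m.normalized,
    )


def inverse_standardize(m: FeatureMatrix) -> FeatureMatrix:
    """Undo z-scoring using the stored parameters."""
    if m.standardization is None:
        raise ParameterError("matrix carries no standardization parameters")
    raw = m.values * m.standardization.sd + m.standardization.mean
    return FeatureMatrix(
        sample_ids=list(m.sample_ids),
        groups=m.groups.copy(),
        feature_mzs=m.feature_mzs.copy(),
        values=raw,
        normalized=m.normalized,
    )


# ---------------------------------------------------------------- pipeline


def preprocess_cohort(spectra: list[Spectrum], manifest: pd.DataFrame,
                      half_window: int = 50, smooth_window: int = 9,
                      smooth_polyorder: int = 3, snr_threshold: float = 3.0,
                      tolerance_ppm: float = 300.0,
                      min_fraction: float = 2.0 / 3.0,
                      impute: str = "zero", normalize: str = "none"
                      ) -> FeatureMatrix:
    """Full chain: baseline → smooth → detect → align → filter → matrix."""
    peaklists = []
    for s in spectra:
        corrected = correct_baseline(s, half_window=half_window)
        smoothed = smooth(corrected, window=smooth_window,
                          polyorder=smooth_polyorder)
        peaklists.append(detect_peaks(smoothed, snr_threshold=snr_threshold,
                                      noise_reference=corrected))
    features = align_peaks(peaklists, tolerance_ppm=tolerance_ppm)
    features = filter_features(features, manifest, min_fraction=min_fraction)
    return build_matrix(features, manifest, impute=impute, normalize=normalize)
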