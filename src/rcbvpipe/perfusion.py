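"""DSC-MRI perfusion quantification.

Pipeline: baseline estimation and conversion of the T2*-weighted signal to
dR2* concentration curves, automatic arterial-input-function (AIF) detection
by iterated cluster analysis, delay-insensitive block-circulant SVD (cSVD)
deconvolution for CBF, rCBV as the ratio of tissue to arterial curve areas,
and Boxerman leakage correction yielding K1/K2 maps and corrected curves.

All quantities are relative (the concentration/dR2* proportionality constant
is taken as 1), which is all the downstream histogram analysis requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import circulant
from sklearn.cluster import KMeans

from .simulate import AcquisitionSpec

__all__ = [
    "DscSeries",
    "ConcentrationSeries",
    "Aif",
    "DeconvolutionConfig",
    "PerfusionMaps",
    "signal_to_delta_r2s",
    "detect_aif",
    "csvd_deconvolve",
    "compute_rcbv",
    "boxerman_correct",
    "quantify_subject",
]


@dataclass
class DscSeries:
    """4-D DSC signal (time first) with acquisition metadata and brain mask."""

    signal: np.ndarray            # (T, Z, Y, X)
    acquisition: AcquisitionSpec
    brain_mask: np.ndarray        # (Z, Y, X) bool

    def __post_init__(self) -> None:
        if self.signal.shape[0] != self.acquisition.n_frames:
            raise ValueError("signal time axis does not match n_frames")
        if self.signal.shape[1:] != tuple(self.acquisition.grid_shape):
            raise ValueError("signal grid does not match acquisition grid")
        if self.brain_mask.shape != self.signal.shape[1:]:
            raise ValueError("brain_mask grid mismatch")


@dataclass
class ConcentrationSeries:
    """Voxelwise dR2*(t) curves plus the baseline S0 volume."""

    delta_r2s: np.ndarray         # (T, Z, Y, X), 1/s
    baseline_s0: np.ndarray       # (Z, Y, X)
    acquisition: AcquisitionSpec
    brain_mask: np.ndarray


@dataclass
class Aif:
    """Arterial input curve, its member voxels, and the curve's first moment."""

    curve: np.ndarray
    member_voxels: list[tuple[int, int, int]]
    first_moment: float


@dataclass
class DeconvolutionConfig:
    """cSVD settings: singular values below ``svd_threshold_frac`` of the
    largest are zeroed; the curves are zero-padded to ``pad_factor * T``."""

    svd_threshold_frac: float = 0.10
    pad_factor: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.svd_threshold_frac < 1.0:
            raise ValueError("svd_threshold_frac must be in (0, 1)")
        if self.pad_factor < 2:
            raise ValueError("pad_factor must be >= 2")


@dataclass
class PerfusionMaps:
    """Voxelwise output maps on the FLAIR grid."""

    rcbv: np.ndarray
    cbf: np.ndarray
    mtt: np.ndarray
    k1: np.ndarray
    k2: np.ndarray


# ---------------------------------------------------------------------------

def signal_to_delta_r2s(dsc: DscSeries, n_baseline: int | None = None
                        ) -> ConcentrationSeries:
    """Convert signal to dR2*(t) = -ln(S(t)/S0)/TE, with S0 the per-voxel mean
    of the pre-bolus baseline frames. Negative values (noise, T1 effects) are
    preserved."""
    if n_baseline is None:
        n_baseline = dsc.acquisition.n_baseline
    if n_baseline < 3:
        raise ValueError("n_baseline must be >= 3")
    s0 = dsc.signal[:n_baseline].mean(axis=0)
    bad = (s0 <= 0) & dsc.brain_mask
    if bad.any():
        z, y, x = [int(v) for v in np.argwhere(bad)[0]]
        raise ValueError(
            f"non-positive baseline S0 inside brain mask at voxel ({z}, {y}, {x})")
    # floor the log argument: deep signal troughs can graze zero in magnitude
    # images, which would otherwise map to infinite dR2*
    floor = 1e-3 * float(s0[dsc.brain_mask].max())
    with np.errstate(divide="ignore", invalid="ignore"):
        dr2s = -np.log(np.maximum(dsc.signal, floor) / s0) / dsc.acquisition.te
    dr2s = np.where(dsc.brain_mask, dr2s, 0.0)
    return ConcentrationSeries(delta_r2s=dr2s, baseline_s0=s0,
                               acquisition=dsc.acquisition,
                               brain_mask=dsc.brain_mask)


def _first_moments(curves: np.ndarray, dt: float) -> np.ndarray:
    """First moment int t*c / int c per curve (rows).

    Computed on the positive part of each curve: leakage gives some voxels a
    negative T1-dominant tail that would otherwise drag the moment to
    arbitrarily small values and masquerade as an early arrival.
    """
    pos = np.maximum(curves, 0.0)
    t = np.arange(curves.shape[1]) * dt
    num = np.trapezoid(pos * t, dx=dt, axis=1)
    den = np.trapezoid(pos, dx=dt, axis=1)
    return num / den


def detect_aif(conc: ConcentrationSeries, k_clusters: int = 5,
               n_rounds: int = 2, random_state: int = 0) -> Aif:
    """Automatic AIF detection by iterated k-means cluster analysis.

    Candidates are in-brain voxels in the top quartile of curve AUC whose
    roughness (sum of squared second differences) is below the candidate
    median. Curves are normalized to unit AUC and clustered; the cluster with
    the earliest mean first moment is kept and re-clustered ``n_rounds - 1``
    more times. The AIF is the mean raw curve over the final members.
    """
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    if not conc.brain_mask.any():
        raise ValueError("brain_mask is empty")
    dt = conc.acquisition.tr
    coords = np.argwhere(conc.brain_mask)
    curves = conc.delta_r2s[:, conc.brain_mask].T          # (N, T)

    auc = np.trapezoid(curves, dx=dt, axis=1)
    keep = auc >= np.quantile(auc, 0.75)
    # drop candidates whose tail does not return to baseline: leakage-affected
    # voxels drift away from zero and must not seed the arterial cluster
    baseline_sd = curves[:, :conc.acquisition.n_baseline].std(axis=1)
    tail_mean = curves[:, -5:].mean(axis=1)
    floor = 1e-8 * max(float(np.abs(curves).max()), 1.0)
    keep &= np.abs(tail_mean) <= 2.0 * baseline_sd + floor
    # Roughness is a noise measure, so it is evaluated on the post-first-pass
    # tail where every curve has returned toward baseline; measured on the
    # full curve it would reject the artery itself, whose first pass is the
    # sharpest structure in the image.
    tail = curves.shape[1] // 3
    rough = np.sum(np.diff(curves[keep, -tail:], n=2, axis=1) ** 2, axis=1)
    smooth = rough <= np.median(rough)
    idx = np.flatnonzero(keep)[smooth]
    if idx.size < k_clusters:
        raise ValueError("too few AIF candidate voxels")

    for round_no in range(max(1, n_rounds)):
        # a further round needs enough voxels per centroid to be meaningful;
        # otherwise k-means would split the arterial cluster by pure noise
        if round_no > 0 and idx.size < 5 * k_clusters:
            break
        sub = curves[idx]
        norm = sub / np.trapezoid(sub, dx=dt, axis=1)[:, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate curves are expected
            labels = KMeans(n_clusters=k_clusters, random_state=random_state,
                            n_init=10).fit_predict(norm)
        fm = _first_moments(sub, dt)
        cluster_fm = [fm[labels == c].mean() if (labels == c).any() else np.inf
                      for c in range(k_clusters)]
        idx = idx[labels == int(np.argmin(cluster_fm))]

    members = curves[idx]
    curve = members.mean(axis=0)
    return Aif(curve=curve,
               member_voxels=[tuple(int(v) for v in coords[i]) for i in idx],
               first_moment=float(_first_moments(members, dt).mean()))


def csvd_deconvolve(tissue: np.ndarray, aif: Aif, dt: float,
                    config: DeconvolutionConfig | None = None
                    ) -> tuple[float, np.ndarray]:
    """Block-circulant (delay-insensitive) SVD deconvolution of one voxel.

    Returns (cbf, residue_scaled) where residue_scaled = CBF*R on the padded
    circular axis and cbf is its maximum, which is invariant to circular
    shifts of the tissue curve.
    """
    if config is None:
        config = DeconvolutionConfig()
    tissue = np.asarray(tissue, dtype=float)
    inv = _csvd_inverse(aif, tissue.size, dt, config)
    padded = np.zeros(inv.shape[0])
    padded[:tissue.size] = tissue
    residue = inv @ padded
    return float(residue.max()), residue


def _csvd_inverse(aif: Aif, n: int, dt: float,
                  config: DeconvolutionConfig) -> np.ndarray:
    """Truncated pseudo-inverse of the padded block-circulant AIF matrix."""
    if np.trapezoid(aif.curve, dx=dt) <= 0:
        raise ValueError("AIF AUC must be positive")
    length = config.pad_factor * n
    col = np.zeros(length)
    col[:n] = dt * aif.curve
    a = circulant(col)
    u, s, vt = np.linalg.svd(a)
    s_inv = np.where(s >= config.svd_threshold_frac * s[0], 1.0 / s, 0.0)
    return (vt.T * s_inv) @ u.T


#: Default rCBV integration span after the baseline, in seconds. The tracer
#: kinetic model applies to the first pass; 50 s covers bolus transit plus
#: full washout for tissue MTTs up to ~6 s, while not accumulating baseline-S0
#: estimation noise over the whole series.
FIRST_PASS_SECONDS = 50.0


def compute_rcbv(conc: ConcentrationSeries, aif: Aif,
                 window: tuple[int, int] | None = None) -> np.ndarray:
    """rCBV = AUC(tissue curve) / AUC(AIF) per voxel over the first-pass
    window; negative values are floored at 0."""
    spec = conc.acquisition
    if window is None:
        end = min(spec.n_frames,
                  spec.n_baseline + int(np.ceil(FIRST_PASS_SECONDS / spec.tr)))
        window = (spec.n_baseline, end)
    lo, hi = window
    dt = spec.tr
    aif_auc = np.trapezoid(aif.curve[lo:hi], dx=dt)
    if aif_auc <= 0:
        raise ValueError("AIF AUC must be positive")
    auc = np.trapezoid(conc.delta_r2s[lo:hi], dx=dt, axis=0)
    rcbv = auc / aif_auc
    return np.where(conc.brain_mask, np.maximum(rcbv, 0.0), 0.0)


def boxerman_correct(conc: ConcentrationSeries,
                     tumor_mask: np.ndarray | None = None,
                     min_reference: int = 50, tail_frames: int = 5
                     ) -> tuple[ConcentrationSeries, np.ndarray, np.ndarray]:
    """Leakage correction with the two-regressor linear model.

    The reference curve is the mean dR2* over non-tumor in-brain voxels whose
    post-bolus tail returns to within 2 baseline-noise SDs of zero. Each voxel
    is fit as measured(t) ~ K1*ref(t) - K2*int_0^t ref, and corrected as
    corrected(t) = measured(t) + K2*int_0^t ref. Returns the corrected series
    plus K1 and K2 volumes.
    """
    spec = conc.acquisition
    dt = spec.tr
    flat = conc.delta_r2s.reshape(spec.n_frames, -1)       # (T, N)
    brain = conc.brain_mask.ravel()
    non_tumor = brain if tumor_mask is None else brain & ~tumor_mask.ravel()
    if non_tumor.sum() < min_reference:
        raise ValueError(
            f"need >= {min_reference} non-tumor brain voxels for the reference")

    baseline_sd = flat[:spec.n_baseline].std(axis=0)
    tail = flat[-tail_frames:].mean(axis=0)
    # absolute floor keeps the rule meaningful in the noise-free limit
    floor = 1e-8 * max(np.abs(flat).max(), 1.0)
    eligible = non_tumor & (np.abs(tail) <= 2.0 * baseline_sd + floor)
    if eligible.sum() < min_reference:
        eligible = non_tumor
    ref = flat[:, eligible].mean(axis=1)
    if np.trapezoid(ref, dx=dt) <= 0:
        raise ValueError("degenerate leakage reference curve (AUC <= 0)")

    cum = cumulative_trapezoid(ref, dx=dt, initial=0.0)
    design = np.column_stack([ref, -cum])                   # (T, 2)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)    # (2, N)
    k1 = np.where(brain, coef[0], 0.0)
    k2 = np.where(brain, coef[1], 0.0)
    corrected = flat + k2[None, :] * cum[:, None]
    corrected = np.where(brain[None, :], corrected, flat)
    shape = (spec.n_frames,) + tuple(spec.grid_shape)
    out = ConcentrationSeries(
        delta_r2s=corrected.reshape(shape), baseline_s0=conc.baseline_s0,
        acquisition=spec, brain_mask=conc.brain_mask)
    return out, k1.reshape(spec.grid_shape), k2.reshape(spec.grid_shape)


def quantify_subject(dsc: DscSeries, tumor_mask: np.ndarray | None = None,
                     config: DeconvolutionConfig | None = None,
                     k_clusters: int = 5, n_rounds: int = 2,
                     random_state: int = 0
                     ) -> tuple[PerfusionMaps, Aif]:
    """Full quantification of one subject.

    signal -> dR2* -> AIF detection -> Boxerman correction -> cSVD CBF map ->
    AUC-ratio rCBV on the corrected curves; MTT = rCBV/CBF (central volume).
    """
    if config is None:
        config = DeconvolutionConfig()
    spec = dsc.acquisition
    conc = signal_to_delta_r2s(dsc)
    aif = detect_aif(conc, k_clusters=k_clusters, n_rounds=n_rounds,
                     random_state=random_state)
    corrected, k1, k2 = boxerman_correct(conc, tumor_mask)
    rcbv = compute_rcbv(corrected, aif)

    inv = _csvd_inverse(aif, spec.n_frames, spec.tr, config)
    flat = corrected.delta_r2s.reshape(spec.n_frames, -1)
    padded = np.zeros((inv.shape[0], flat.shape[1]))
    padded[:spec.n_frames] = flat
    residues = inv @ padded
    cbf = residues.max(axis=0).reshape(spec.grid_shape)
    cbf = np.where(dsc.brain_mask, np.maximum(cbf, 0.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(cbf > 0, rcbv / cbf, 0.0)
    maps = PerfusionMaps(rcbv=rcbv, cbf=cbf, mtt=mtt, k1=k1, k2=k2)
    return maps, aif
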