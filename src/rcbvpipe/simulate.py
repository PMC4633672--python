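"""Synthetic DSC-MRI subjects and two-genotype cohorts with known ground truth.

The simulator produces the forward model that the quantification stage
inverts: a gamma-variate arterial bolus, tissue concentration curves from the
convolution C(t) = CBF * (Ca (x) R)(t) with an exponential residue function
R(t) = exp(-t/MTT), conversion to T2*-weighted signal S = S0 * exp(-TE * dR2*),
and (optionally) contrast-agent leakage injected with the linear two-regressor
model that the Boxerman correction removes.

Cohorts carry two genotype classes (IDH-1/2 mutant vs. wild-type) whose tumor
rCBV distributions are controlled at the subject level by a log-normal over
subject median rCBV and at the voxel level by a Gamma distribution scaled to
the subject median. Every subject records its ground-truth perfusion maps so
downstream stages can be tested for parameter recovery without patient data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import nibabel as nib
import pandas as pd
from scipy import stats as sps
from scipy.integrate import cumulative_trapezoid
from scipy.signal import fftconvolve

__all__ = [
    "AcquisitionSpec",
    "KineticParams",
    "GroundTruth",
    "SyntheticSubject",
    "CohortSpec",
    "gamma_variate_curve",
    "tissue_concentration",
    "concentration_to_signal",
    "apply_leakage",
    "sample_subject_median",
    "sample_tumor_rcbv",
    "simulate_cohort_rcbv",
    "synthesize_subject",
    "synthesize_cohort",
    "write_subject",
    "write_cohort",
]

GENOTYPES = ("mutant", "wildtype")

#: z-score of the 75th normal percentile, used to convert an IQR into the
#: sigma of the underlying log-normal.
_Z75 = sps.norm.ppf(0.75)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSpec:
    """DSC acquisition geometry and timing.

    Defaults mirror a standard low-grade-glioma perfusion protocol
    (TE = 36 ms, TR = 2.22 s, 60 dynamic frames) on a desk-scale grid.
    """

    tr: float = 2.22
    te: float = 0.036
    n_frames: int = 60
    n_baseline: int = 8
    grid_shape: tuple[int, int, int] = (4, 48, 48)

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.te <= 0:
            raise ValueError("tr and te must be positive")
        if self.n_frames < self.n_baseline + 10:
            raise ValueError("n_frames must be at least n_baseline + 10")
        if len(self.grid_shape) != 3 or any(d < 1 for d in self.grid_shape):
            raise ValueError("grid_shape must be three dimensions, all >= 1")

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.tr


@dataclass
class KineticParams:
    """Per-voxel (or per-bolus) kinetic parameters of the forward model."""

    t0: float = 22.2          # bolus arrival (s)
    alpha: float = 3.0        # gamma-variate shape
    beta: float = 1.5         # gamma-variate scale (s)
    amplitude: float = 20.0   # peak arterial dR2* (1/s)
    cbf: float = 0.25         # flow, relative units (1/s scale)
    mtt: float = 4.0          # mean transit time (s)
    k2_leak: float = 0.0      # leakage rate (1/s)
    k1_leak: float = 1.0      # leakage scale factor (dimensionless)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.mtt <= 0:
            raise ValueError("mtt must be positive")
        if self.cbf < 0 or self.k2_leak < 0:
            raise ValueError("cbf and k2_leak must be non-negative")


@dataclass
class GroundTruth:
    """Voxelwise truth maps for one subject (central volume: cbv = cbf*mtt)."""

    cbv_map: np.ndarray
    cbf_map: np.ndarray
    mtt_map: np.ndarray
    k2_map: np.ndarray
    tumor_mask: np.ndarray
    genotype: str


@dataclass
class SyntheticSubject:
    """One simulated patient: 4-D DSC signal, FLAIR, and ground truth."""

    dsc: "DscSeries"  # forward reference; defined in rcbvpipe.perfusion
    flair: np.ndarray
    truth: GroundTruth
    subject_id: str


@dataclass
class CohortSpec:
    """Study-level generator settings.

    The class targets are the subject-level tumor rCBV medians / IQRs of the
    two genotype groups; defaults encode the separation seen between IDH-1/2
    mutant and wild-type low-grade/anaplastic gliomas (mutant tumors cluster
    at markedly lower rCBV). Class sizes default to the mutant predominance
    typical of treatment-naive low-grade glioma cohorts.
    """

    n_mutant: int = 59
    n_wildtype: int = 14
    class_rcbv_median: dict = field(
        default_factory=lambda: {"mutant": 1.09, "wildtype": 2.08})
    class_rcbv_iqr: dict = field(
        default_factory=lambda: {"mutant": (0.80, 1.47),
                                 "wildtype": (1.49, 2.57)})
    #: Gamma shape of the voxel-level rCBV distribution per class. Wild-type
    #: tumors get a lower shape (heavier right tail): angiogenic hotspots make
    #: them more heterogeneous, which concentrates class separation in the
    #: upper histogram percentiles.
    voxel_gamma_shape: dict = field(
        default_factory=lambda: {"mutant": 4.0, "wildtype": 2.0})
    leak_fraction: float = 0.25
    noise_sd: float = 20.0    # Gaussian signal noise (baseline SNR 50 at s0=1000)
    s0: float = 1000.0        # baseline signal level
    tumor_radii: tuple[float, float, float] = (1.2, 9.0, 9.0)  # voxels (z,y,x)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutant < 2 or self.n_wildtype < 2:
            raise ValueError("need at least 2 subjects per class")
        if not 0.0 <= self.leak_fraction <= 1.0:
            raise ValueError("leak_fraction must be in [0, 1]")
        for g in GENOTYPES:
            q1, q3 = self.class_rcbv_iqr[g]
            med = self.class_rcbv_median[g]
            if not q1 < med < q3:
                raise ValueError(f"{g}: require q1 < median < q3")


# ---------------------------------------------------------------------------
# kinetic primitives
# ---------------------------------------------------------------------------

def gamma_variate_curve(params: KineticParams, time_axis: np.ndarray) -> np.ndarray:
    """Peak-normalized gamma-variate bolus curve.

    c(t) = amplitude * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta)
    for t > t0, else 0. The maximum equals ``amplitude`` at t = t0 + alpha*beta.
    """
    time_axis = np.asarray(time_axis, dtype=float)
    if time_axis.ndim != 1 or time_axis.size < 2:
        raise ValueError("time_axis must be a 1-D vector")
    if time_axis[0] != 0 or np.any(np.diff(time_axis) <= 0):
        raise ValueError("time_axis must start at 0 and be strictly increasing")
    if params.alpha <= 0 or params.beta <= 0:
        raise ValueError("alpha and beta must be positive")
    tau = time_axis - params.t0
    curve = np.zeros_like(time_axis)
    up = tau > 0
    x = tau[up] / (params.alpha * params.beta)
    curve[up] = params.amplitude * x ** params.alpha * np.exp(
        params.alpha - tau[up] / params.beta)
    return curve


def tissue_concentration(aif_curve: np.ndarray, cbf: float, mtt: float,
                         dt: float) -> np.ndarray:
    """Forward tissue model C(t) = CBF * (Ca (x) R)(t), R(t) = exp(-t/MTT).

    Discrete convolution with trapezoidal weighting on a uniform grid of
    spacing ``dt``. The returned curve has the same length as the input and
    satisfies AUC(C)/AUC(Ca) = cbf*mtt up to discretization error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if mtt <= 0:
        raise ValueError("mtt must be positive")
    aif_curve = np.asarray(aif_curve, dtype=float)
    n = aif_curve.size
    t = np.arange(n) * dt
    residue = np.exp(-t / mtt)
    conv = fftconvolve(aif_curve, residue)[:n] * dt
    # trapezoid end correction: half-weight the j=0 and j=i endpoints
    conv -= 0.5 * dt * (aif_curve[0] * residue + aif_curve * residue[0])
    return cbf * conv


def concentration_to_signal(delta_r2s: np.ndarray, s0: float, te: float) -> np.ndarray:
    """T2* signal model S(t) = S0 * exp(-TE * dR2*(t))."""
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if te <= 0:
        raise ValueError("te must be positive")
    return s0 * np.exp(-te * np.asarray(delta_r2s, dtype=float))


def apply_leakage(delta_r2s: np.ndarray, k1: float, k2: float,
                  reference_curve: np.ndarray, dt: float) -> np.ndarray:
    """Inject the linear leakage model the Boxerman correction removes.

    out(t) = k1 * dR2*(t) - k2 * int_0^t ref(tau) dtau (cumulative trapezoid).
    Negative outputs (T1-dominant leakage) are preserved.
    """
    delta_r2s = np.asarray(delta_r2s, dtype=float)
    reference_curve = np.asarray(reference_curve, dtype=float)
    cum = cumulative_trapezoid(reference_curve, dx=dt, initial=0.0)
    return k1 * delta_r2s - k2 * cum


# ---------------------------------------------------------------------------
# cohort-level rCBV distributions (truth layer)
# ---------------------------------------------------------------------------

def _lognormal_params(cohort: CohortSpec, genotype: str) -> tuple[float, float]:
    """(mu, sigma) of the subject-median log-normal fitted to median + IQR."""
    med = cohort.class_rcbv_median[genotype]
    q1, q3 = cohort.class_rcbv_iqr[genotype]
    mu = np.log(med)
    sigma = (np.log(q3) - np.log(q1)) / (2.0 * _Z75)
    return mu, sigma


def sample_subject_median(rng: np.random.Generator, cohort: CohortSpec,
                          genotype: str) -> float:
    """Draw one subject's tumor rCBV median from the class log-normal."""
    mu, sigma = _lognormal_params(cohort, genotype)
    return float(np.exp(rng.normal(mu, sigma)))


def sample_tumor_rcbv(rng: np.random.Generator, subject_median: float,
                      gamma_shape: float, n_voxels: int) -> np.ndarray:
    """Voxel-level rCBV draws: Gamma(shape) rescaled so the population median
    equals ``subject_median`` (right-skewed, strictly positive)."""
    scale = subject_median / sps.gamma.ppf(0.5, gamma_shape)
    return rng.gamma(gamma_shape, scale, size=n_voxels)


def simulate_cohort_rcbv(cohort: CohortSpec, n_voxels: int = 600,
                         rng: np.random.Generator | None = None) -> list[dict]:
    """Truth-layer cohort: per-subject tumor rCBV voxel samples, no imaging.

    This is the same distributional layer :func:`synthesize_subject` uses to
    assign tumor voxel truth; it supports statistics-only experiments (large
    replicate counts) without paying for image synthesis.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.seed)
    subjects = []
    idx = 0
    for genotype, n in (("wildtype", cohort.n_wildtype),
                        ("mutant", cohort.n_mutant)):
        for _ in range(n):
            med = sample_subject_median(rng, cohort, genotype)
            vals = sample_tumor_rcbv(
                rng, med, cohort.voxel_gamma_shape[genotype], n_voxels)
            subjects.append({
                "subject_id": f"sub-{idx:03d}",
                "genotype": genotype,
                "values": vals,
            })
            idx += 1
    return subjects


# ---------------------------------------------------------------------------
# full image synthesis
# ---------------------------------------------------------------------------

_MTT_GRID = np.round(np.arange(3.0, 6.0 + 1e-9, 0.05), 2)  # seconds
_FINE_SUBDIV = 16          # internal time-grid refinement per TR
_ARTERY_BLOCK = (slice(0, 2), slice(0, 4), slice(0, 4))
_ARTERY_EARLY_FRAMES = 2.0  # arterial t0 leads tissue t0 by this many TR
_ARTERY_BETA = 1.0          # narrower bolus in the artery (low dispersion)
#: Non-tumor parenchyma rCBV range: the raw tissue-to-arterial AUC ratio of
#: normal white/gray matter sits below 1, with tumor values rising above it.
_NORMAL_RCBV_RANGE = (0.5, 0.9)
_FLAIR_BACKGROUND = 100.0
_FLAIR_TUMOR = 150.0        # +50% over background


def _tumor_mask(spec: AcquisitionSpec, radii: tuple[float, float, float]) -> np.ndarray:
    """Ellipsoidal tumor centered on the grid."""
    zz, yy, xx = np.meshgrid(*[np.arange(d) for d in spec.grid_shape],
                             indexing="ij")
    center = [(d - 1) / 2.0 for d in spec.grid_shape]
    d2 = sum(((g - c) / r) ** 2
             for g, c, r in zip((zz, yy, xx), center, radii))
    return d2 <= 1.0


def _frame_sampled_tissue_curves(spec: AcquisitionSpec, bolus: KineticParams,
                                 mtt_values: np.ndarray) -> np.ndarray:
    """Tissue curve per unique mtt (unit CBF), convolved on a fine internal
    grid and sampled at frame times. Shape (len(mtt_values), n_frames)."""
    dt_fine = spec.tr / _FINE_SUBDIV
    n_fine = (spec.n_frames - 1) * _FINE_SUBDIV + 1
    t_fine = np.arange(n_fine) * dt_fine
    ca_fine = gamma_variate_curve(bolus, t_fine)
    out = np.empty((mtt_values.size, spec.n_frames))
    frame_idx = np.arange(spec.n_frames) * _FINE_SUBDIV
    for i, mtt in enumerate(mtt_values):
        c = tissue_concentration(ca_fine, 1.0, float(mtt), dt_fine)
        out[i] = c[frame_idx]
    return out


def synthesize_subject(spec: AcquisitionSpec, cohort: CohortSpec, genotype: str,
                       rng: np.random.Generator,
                       subject_id: str = "sub-000") -> SyntheticSubject:
    """Generate one subject: DSC 4-D signal, FLAIR, and ground truth.

    Tumor voxels draw per-voxel rCBV from the genotype's class distribution
    (split into cbf = rcbv/mtt with mtt from a discrete 3-6 s grid); non-tumor
    brain voxels carry reference-tissue kinetics (rCBV near 1); a small corner
    block carries arterial kinetics (earlier arrival, full bolus amplitude) so
    automatic AIF detection has a findable target. A ``leak_fraction`` of
    tumor voxels receives linear leakage against the mean non-tumor curve.
    """
    from .perfusion import DscSeries  # deferred to avoid a module cycle

    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    gz, gy, gx = spec.grid_shape
    tumor = _tumor_mask(spec, cohort.tumor_radii)
    if not tumor.any():
        raise ValueError("grid too small for the configured tumor radii")
    artery = np.zeros(spec.grid_shape, dtype=bool)
    artery[_ARTERY_BLOCK] = True
    if (artery & tumor).any() or artery.sum() == 0:
        raise ValueError("grid too small to place artery and tumor apart")

    n_vox = int(np.prod(spec.grid_shape))
    tumor_flat = tumor.ravel()
    artery_flat = artery.ravel()
    tissue_flat = ~tumor_flat & ~artery_flat

    # --- truth maps -------------------------------------------------------
    mtt_map = rng.choice(_MTT_GRID, size=n_vox)
    cbv = np.empty(n_vox)
    subj_median = sample_subject_median(rng, cohort, genotype)
    cbv[tumor_flat] = sample_tumor_rcbv(
        rng, subj_median, cohort.voxel_gamma_shape[genotype],
        int(tumor_flat.sum()))
    cbv[~tumor_flat] = rng.uniform(*_NORMAL_RCBV_RANGE,
                                   size=int((~tumor_flat).sum()))
    cbf = cbv / mtt_map

    # --- noise-free concentration curves ---------------------------------
    bolus = KineticParams(t0=10.0 * spec.tr)
    unique_mtt, inv = np.unique(mtt_map, return_inverse=True)
    base_curves = _frame_sampled_tissue_curves(spec, bolus, unique_mtt)
    conc = base_curves[inv] * cbf[:, None]          # (n_vox, T)

    # Arterial voxels: earlier arrival, narrower bolus (low dispersion, hence
    # higher peak), scaled so the frame-sampled curve carries exactly the same
    # trapezoidal AUC as the tissue-generating bolus — the AIF the detector
    # finds is then the consistent normalizer for the AUC-ratio rCBV.
    artery_bolus = KineticParams(
        t0=(10.0 - _ARTERY_EARLY_FRAMES) * spec.tr, beta=_ARTERY_BETA,
        amplitude=bolus.amplitude)
    artery_frames = gamma_variate_curve(artery_bolus, spec.times)
    ca_frames = gamma_variate_curve(bolus, spec.times)
    artery_frames *= (np.trapezoid(ca_frames, dx=spec.tr)
                      / np.trapezoid(artery_frames, dx=spec.tr))
    conc[artery_flat] = artery_frames
    cbv[artery_flat] = 1.0
    mtt_map[artery_flat] = _MTT_GRID[0]
    cbf[artery_flat] = cbv[artery_flat] / mtt_map[artery_flat]

    # --- leakage ----------------------------------------------------------
    # Reference = mean over non-tumor in-brain voxels, the same definition the
    # corrector uses, so the linear model is exactly invertible downstream.
    reference = conc[~tumor_flat].mean(axis=0)
    k2_map = np.zeros(n_vox)
    n_leaky = int(round(cohort.leak_fraction * tumor_flat.sum()))
    if n_leaky > 0:
        leaky_idx = rng.choice(np.flatnonzero(tumor_flat), size=n_leaky,
                               replace=False)
        k2_map[leaky_idx] = rng.uniform(0.01, 0.1, size=n_leaky)
        cum = cumulative_trapezoid(reference, dx=spec.tr, initial=0.0)
        conc[leaky_idx] = conc[leaky_idx] - k2_map[leaky_idx, None] * cum[None, :]

    # --- signal + noise ---------------------------------------------------
    signal = concentration_to_signal(conc, cohort.s0, spec.te)
    if cohort.noise_sd > 0:
        # magnitude images: MR signal is Rician, never negative
        signal = np.abs(signal + rng.normal(0.0, cohort.noise_sd,
                                            size=signal.shape))

    # --- FLAIR ------------------------------------------------------------
    flair = np.full(spec.grid_shape, _FLAIR_BACKGROUND)
    flair[tumor] = _FLAIR_TUMOR
    if cohort.noise_sd > 0:
        # mild texture noise, 2% of background, only in the noisy regime
        flair = flair + rng.normal(0.0, 0.02 * _FLAIR_BACKGROUND,
                                   size=spec.grid_shape)

    reshape = lambda a: a.reshape(spec.grid_shape)
    truth = GroundTruth(
        cbv_map=reshape(cbv), cbf_map=reshape(cbf), mtt_map=reshape(mtt_map),
        k2_map=reshape(k2_map), tumor_mask=tumor, genotype=genotype)
    dsc = DscSeries(
        signal=np.moveaxis(signal.reshape(spec.grid_shape + (spec.n_frames,)),
                           -1, 0),
        acquisition=spec,
        brain_mask=np.ones(spec.grid_shape, dtype=bool))
    return SyntheticSubject(dsc=dsc, flair=flair, truth=truth,
                            subject_id=subject_id)


def synthesize_cohort(spec: AcquisitionSpec, cohort: CohortSpec
                      ) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Simulate the full cohort; returns subjects plus a (subject_id, genotype)
    table. Deterministic for a fixed ``cohort.seed``."""
    ss = np.random.SeedSequence(cohort.seed)
    n_total = cohort.n_wildtype + cohort.n_mutant
    children = ss.spawn(n_total)
    subjects = []
    rows = []
    idx = 0
    for genotype, n in (("wildtype", cohort.n_wildtype),
                        ("mutant", cohort.n_mutant)):
        for _ in range(n):
            sid = f"sub-{idx:03d}"
            rng = np.random.default_rng(children[idx])
            subjects.append(synthesize_subject(spec, cohort, genotype, rng, sid))
            rows.append({"subject_id": sid, "genotype": genotype})
            idx += 1
    return subjects, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI / CSV export
# ---------------------------------------------------------------------------

def _save_nifti(data: np.ndarray, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4))
    nib.save(img, str(path))


def write_subject(subject: SyntheticSubject, out_dir: str | Path) -> dict:
    """Write one subject's volumes + JSON sidecar; returns the file map."""
    out = Path(out_dir) / subject.subject_id
    out.mkdir(parents=True, exist_ok=True)
    spec = subject.dsc.acquisition
    files = {
        "dsc": out / "dsc.nii.gz",
        "flair": out / "flair.nii.gz",
        "truth_cbv": out / "truth_cbv.nii.gz",
        "truth_cbf": out / "truth_cbf.nii.gz",
        "truth_mtt": out / "truth_mtt.nii.gz",
        "truth_k2": out / "truth_k2.nii.gz",
        "truth_mask": out / "truth_mask.nii.gz",
    }
    # NIfTI stores time as the last axis
    _save_nifti(np.moveaxis(subject.dsc.signal, 0, -1), files["dsc"])
    _save_nifti(subject.flair, files["flair"])
    _save_nifti(subject.truth.cbv_map, files["truth_cbv"])
    _save_nifti(subject.truth.cbf_map, files["truth_cbf"])
    _save_nifti(subject.truth.mtt_map, files["truth_mtt"])
    _save_nifti(subject.truth.k2_map, files["truth_k2"])
    _save_nifti(subject.truth.tumor_mask.astype(np.float32), files["truth_mask"])
    sidecar = out / "acquisition.json"
    sidecar.write_text(json.dumps(
        {"subject_id": subject.subject_id,
         "genotype": subject.truth.genotype,
         "acquisition": asdict(spec)}, indent=2))
    files["sidecar"] = sidecar
    return {k: str(v) for k, v in files.items()}


def write_cohort(subjects: list[SyntheticSubject], table: pd.DataFrame,
                 out_dir: str | Path) -> Path:
    """Write all subjects plus cohort.csv; returns the cohort table path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_subject(s, out)
    path = out / "cohort.csv"
    table.to_csv(path, index=False)
    return path
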