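"""Synthetic DWI/ADC lesion cohorts with class-specific diffusivity texture.

Each simulated lesion is a star-convex blob whose latent ADC field is a
Gaussian random field (white noise convolved with a Gaussian kernel, variance
renormalized) with a class-specific mean, standard deviation and correlation
length; the surrounding tissue is fluid-like (higher ADC) with its own
texture, and a peritumoral rim of intermediate values separates the two.  The
b = 0 and b = 1000 s/mm^2 signals are derived from the latent field with
additive Gaussian noise, and the reported ADC map is recomputed from that
noisy signal pair — exactly as a scanner would — so signal noise propagates
into the analysis substrate.

Two masks accompany every lesion: the exact rasterized blob ("segmented on
the ADC map") and a dilated variant including the rim ("segmented on high-b
DWI and propagated"), which lets the pipeline compare the two historical
segmentation approaches on data with a known ground truth.

The correlation length ``corr_length`` is defined as the lag at which the
field's autocorrelation falls to exp(-1/2); the smoothing kernel sigma is
corr_length / sqrt(2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import InvalidRoiError
from .io_formats import (
    MASK_ADC,
    MASK_DWI,
    AnnotatedImage,
    CohortManifest,
    LesionRecord,
    ManifestEntry,
    Modality,
    RoiMask,
    write_image,
    write_mask,
)

#: Diffusion sensitization of the high-b acquisition, s/mm^2.
B_VALUE = 1000.0

#: Baseline (b=0) signal level in arbitrary units.
S0 = 600.0

#: Signals are floored at this fraction of S0 before the log (noise can push
#: the high-b signal to zero); clips are counted per lesion.
SIGNAL_FLOOR_FRACTION = 1e-4


@dataclass(frozen=True)
class ClassSpec:
    """Generative parameters of one lesion class.

    ADC units are mm^2/s (typical malignant breast tissue ~1.0e-3);
    ``corr_length`` is in pixels.  ``ar_params`` optionally replaces the
    Gaussian random field with a causal AR texture for parameter-recovery
    experiments.
    """

    label: str
    adc_mean: float = 1.0e-3
    adc_sd: float = 1.2e-4
    corr_length: float = 2.0
    radius_range: tuple[float, float] = (7.0, 11.0)
    ar_params: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.adc_sd < 0:
            raise ValueError("adc_sd must be >= 0")
        if self.corr_length <= 0:
            raise ValueError("corr_length must be > 0")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ValueError("invalid radius range")


#: Background (non-lesion) tissue: fluid-like, high diffusivity.
BACKGROUND = ClassSpec(label="background", adc_mean=2.4e-3, adc_sd=1.5e-4, corr_length=2.0)


def default_class_specs() -> tuple[ClassSpec, ...]:
    """Four molecular-subtype stand-ins with distinct diffusivity texture.

    Mean ADC values sit in the malignant breast-lesion range; the classes
    differ in mean, heterogeneity and spatial correlation length, emulating
    the hypothesis that subtypes differ in the spatial structure of their
    diffusivity rather than in any single summary value.
    """
    return (
        ClassSpec("luminal_A", adc_mean=0.95e-3, adc_sd=1.0e-4, corr_length=2.8),
        ClassSpec("luminal_B", adc_mean=1.00e-3, adc_sd=1.6e-4, corr_length=1.2),
        ClassSpec("HER2_enriched", adc_mean=1.12e-3, adc_sd=1.3e-4, corr_length=3.6),
        ClassSpec("triple_negative", adc_mean=1.28e-3, adc_sd=1.1e-4, corr_length=1.9),
    )


#: Cohort mix observed in the clinical population the simulator emulates.
DEFAULT_N_PER_CLASS = (49, 8, 11, 23)


# ---------------------------------------------------------------------------
# Random fields and masks
# ---------------------------------------------------------------------------

_kernel_norm_cache: dict[tuple[float, tuple[int, int]], float] = {}


def _kernel_norm(sigma: float, shape: tuple[int, int]) -> float:
    key = (round(sigma, 9), shape)
    if key not in _kernel_norm_cache:
        impulse = np.zeros(shape)
        impulse[shape[0] // 2, shape[1] // 2] = 1.0
        k = ndimage.gaussian_filter(impulse, sigma, mode="wrap")
        _kernel_norm_cache[key] = float(np.sqrt((k**2).sum()))
    return _kernel_norm_cache[key]


def gaussian_random_field(shape: tuple[int, int], corr_length: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary field with Gaussian autocorrelation.

    White noise is convolved (periodically) with a Gaussian kernel of
    sigma = corr_length / sqrt(2) and divided by the kernel's l2 norm, so the
    marginal variance is one and the autocorrelation at lag d is
    exp(-d^2 / (2 * corr_length^2)).
    """
    sigma = corr_length / math.sqrt(2.0)
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    return f / _kernel_norm(sigma, shape)


def _causal_ar_field(shape: tuple[int, int], theta: tuple[float, float, float, float], rng: np.random.Generator) -> np.ndarray:
    """Causal AR texture x(i,j) = th.x(neighbours) + e, normalized to unit SD."""
    t1, t2, t3, t4 = theta
    nr, nc = shape
    pad = np.zeros((nr + 1, nc + 2))
    e = rng.standard_normal((nr, nc))
    for i in range(nr):
        for j in range(nc):
            pad[i + 1, j + 1] = (
                t1 * pad[i + 1, j]
                + t2 * pad[i, j + 1]
                + t3 * pad[i, j]
                + t4 * pad[i, j + 2]
                + e[i, j]
            )
    f = pad[1:, 1:-1]
    sd = f.std()
    return f / sd if sd > 0 else f


def make_lesion_mask(
    rng: np.random.Generator,
    radius_range: tuple[float, float],
    image_shape: tuple[int, int],
    max_perturbation: float = 0.3,
    max_retries: int = 50,
) -> RoiMask:
    """Rasterize a star-convex blob: radius(theta) = R*(1 + low-order sinusoids).

    The perturbation is clipped to ``+/- max_perturbation`` of R.  Resamples
    (bounded retries) until the mask is a single 8-connected component of at
    least 16 pixels that fits the image.
    """
    nr, nc = image_shape
    cy, cx = (nr - 1) / 2.0, (nc - 1) / 2.0
    yy, xx = np.mgrid[0:nr, 0:nc]
    rho = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    for _ in range(max_retries):
        R = rng.uniform(*radius_range)
        if R * (1 + max_perturbation) > min(cy, cx):
            R = min(cy, cx) / (1 + max_perturbation)
        pert = np.zeros_like(theta)
        for m in (2, 3, 4):
            a, b = rng.uniform(-0.08, 0.08, size=2)
            pert += a * np.cos(m * theta) + b * np.sin(m * theta)
        np.clip(pert, -max_perturbation, max_perturbation, out=pert)
        inside = rho <= R * (1.0 + pert)
        try:
            return RoiMask(mask=inside)
        except InvalidRoiError:
            continue
    raise InvalidRoiError("could not generate a valid lesion mask; radius range too small?")


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------

@dataclass
class LesionImages:
    """The simulated signal pair, the derived ADC map and bookkeeping."""

    b0: AnnotatedImage
    high_b: AnnotatedImage
    adc: AnnotatedImage
    adc_latent: np.ndarray
    n_clipped: int


def simulate_lesion_images(
    mask: RoiMask,
    spec: ClassSpec,
    rng: np.random.Generator,
    *,
    rim_width: int = 2,
    snr: float | None = 50.0,
    spacing: tuple[float, float] = (1.4, 1.4),
    background: ClassSpec = BACKGROUND,
    lesion_id: str = "",
) -> LesionImages:
    """Simulate the (b0, high-b, ADC) triple for one lesion.

    The latent ADC field is assembled from three regions (lesion, rim of
    ``rim_width`` pixels, background), each mean + SD * GRF(corr_length); the
    rim takes intermediate "peritumoral" values.  Signals are
    b0 = S0 + noise and high_b = S0*exp(-b*ADC) + noise with noise SD
    S0/snr (``snr=None`` disables noise); the reported ADC map is
    ln(b0/high_b)/b recomputed from the noisy pair, with signals floored
    before the log (clips counted).
    """
    m = mask.mask
    shape = m.shape
    if spec.ar_params is not None:
        lesion_field = _causal_ar_field(shape, spec.ar_params, rng)
    else:
        lesion_field = gaussian_random_field(shape, spec.corr_length, rng)
    bg_field = gaussian_random_field(shape, background.corr_length, rng)
    rim_field = gaussian_random_field(shape, background.corr_length, rng)

    dilated = ndimage.binary_dilation(m, structure=np.ones((3, 3), bool), iterations=rim_width)
    rim = dilated & ~m
    rim_mean = 0.5 * (spec.adc_mean + background.adc_mean)
    rim_sd = 0.5 * (spec.adc_sd + background.adc_sd)

    adc_latent = background.adc_mean + background.adc_sd * bg_field
    adc_latent[rim] = rim_mean + rim_sd * rim_field[rim]
    adc_latent[m] = spec.adc_mean + spec.adc_sd * lesion_field[m]

    b0 = np.full(shape, S0)
    high_b = S0 * np.exp(-B_VALUE * adc_latent)
    if snr is not None:
        sigma = S0 / snr
        b0 = b0 + sigma * rng.standard_normal(shape)
        high_b = high_b + sigma * rng.standard_normal(shape)
    floor = S0 * SIGNAL_FLOOR_FRACTION
    n_clipped = int(np.sum(b0 < floor) + np.sum(high_b < floor))
    b0 = np.maximum(b0, floor)
    high_b = np.maximum(high_b, floor)
    adc_map = np.log(b0 / high_b) / B_VALUE

    mk = lambda px, mod: AnnotatedImage(pixels=px, spacing=spacing, modality=mod, id=lesion_id)
    return LesionImages(
        b0=mk(b0, Modality.B0),
        high_b=mk(high_b, Modality.DWI_HIGH_B),
        adc=mk(adc_map, Modality.ADC),
        adc_latent=adc_latent,
        n_clipped=n_clipped,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLesion:
    """One simulated lesion with both mask variants and its signal images."""

    lesion_id: str
    label: str
    images: LesionImages
    true_mask: RoiMask       # exact blob: "drawn on the ADC map"
    dilated_mask: RoiMask    # blob + rim: "propagated from high-b DWI"

    def record(self) -> LesionRecord:
        return LesionRecord(
            lesion_id=self.lesion_id,
            image=self.images.adc,
            masks={MASK_ADC: self.true_mask, MASK_DWI: self.dilated_mask},
            label=self.label,
        )


@dataclass
class SyntheticCohort:
    """A reproducible simulated cohort plus its full generation record."""

    lesions: list[SyntheticLesion]
    specs: tuple[ClassSpec, ...]
    seed: int
    rim_width: int
    snr: float | None
    image_shape: tuple[int, int]
    spacing: tuple[float, float]
    contrasts: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.specs)

    def records(self) -> list[LesionRecord]:
        return [l.record() for l in self.lesions]

    def params_dict(self) -> dict:
        return {
            "seed": self.seed,
            "rim_width": self.rim_width,
            "snr": self.snr,
            "image_shape": list(self.image_shape),
            "spacing": list(self.spacing),
            "b_value": B_VALUE,
            "s0": S0,
            "classes": [
                {
                    "label": s.label,
                    "adc_mean": s.adc_mean,
                    "adc_sd": s.adc_sd,
                    "corr_length": s.corr_length,
                    "radius_range": list(s.radius_range),
                    "ar_params": list(s.ar_params) if s.ar_params else None,
                }
                for s in self.specs
            ],
        }

    def write(self, outdir) -> CohortManifest:
        """Write NIfTI images/masks, a JSON manifest and the parameter record."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        entries = []
        for les in self.lesions:
            stem = les.lesion_id
            write_image(les.images.adc, outdir / f"{stem}_adc.nii.gz")
            write_image(les.images.b0, outdir / f"{stem}_b0.nii.gz")
            write_image(les.images.high_b, outdir / f"{stem}_dwi.nii.gz")
            write_mask(les.true_mask, outdir / f"{stem}_mask_adc.nii.gz", self.spacing)
            write_mask(les.dilated_mask, outdir / f"{stem}_mask_dwi.nii.gz", self.spacing)
            entries.append(
                ManifestEntry(
                    lesion_id=stem,
                    image_path=f"{stem}_adc.nii.gz",
                    mask_paths={
                        MASK_ADC: f"{stem}_mask_adc.nii.gz",
                        MASK_DWI: f"{stem}_mask_dwi.nii.gz",
                    },
                    label=les.label,
                )
            )
        manifest = CohortManifest(
            entries=entries, classes=self.classes, contrasts=dict(self.contrasts),
            base_dir=outdir,
        )
        manifest.to_json(outdir / "manifest.json")
        (outdir / "generation_params.json").write_text(
            json.dumps(self.params_dict(), indent=2) + "\n"
        )
        return manifest


def make_cohort(
    specs: tuple[ClassSpec, ...] | None = None,
    n_per_class: tuple[int, ...] | None = None,
    *,
    rim_width: int = 2,
    seed: int = 0,
    image_shape: tuple[int, int] = (48, 48),
    spacing: tuple[float, float] = (1.4, 1.4),
    snr: float | None = 50.0,
    contrasts: dict[str, tuple[str, ...]] | None = None,
) -> SyntheticCohort:
    """Generate a cohort: ``n_per_class[i]`` lesions from ``specs[i]``.

    Fully reproducible from ``seed``; defaults reproduce the four-subtype mix
    (49, 8, 11, 23) of the clinical population the simulator emulates.
    """
    if specs is None:
        specs = default_class_specs()
    if n_per_class is None:
        n_per_class = DEFAULT_N_PER_CLASS[: len(specs)]
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    if len(n_per_class) != len(specs):
        raise ValueError("n_per_class must match specs")
    rng = np.random.default_rng(seed)
    lesions = []
    for spec, n in zip(specs, n_per_class):
        for i in range(n):
            lesion_id = f"{spec.label}_{i:03d}"
            mask = make_lesion_mask(rng, spec.radius_range, image_shape)
            mask = replace(mask, id=lesion_id)
            images = simulate_lesion_images(
                mask, spec, rng, rim_width=rim_width, snr=snr, spacing=spacing,
                lesion_id=lesion_id,
            )
            dilated = ndimage.binary_dilation(
                mask.mask, structure=np.ones((3, 3), bool), iterations=rim_width
            )
            lesions.append(
                SyntheticLesion(
                    lesion_id=lesion_id,
                    label=spec.label,
                    images=images,
                    true_mask=mask,
                    dilated_mask=RoiMask(mask=dilated, id=f"{lesion_id}_dilated"),
                )
            )
    return SyntheticCohort(
        lesions=lesions,
        specs=tuple(specs),
        seed=seed,
        rim_width=rim_width,
        snr=snr,
        image_shape=image_shape,
        spacing=spacing,
        contrasts=dict(contrasts or {}),
    )


def make_planted_feature_table(
    rng: np.random.Generator,
    n_per_class: int = 25,
    n_features: int = 50,
    n_informative: int = 10,
    effect: float = 2.0,
):
    """A two-class Gaussian feature table with planted informative features.

    The first ``n_informative`` features differ between classes by ``effect``
    pooled standard deviations; the rest are label-independent noise.  Used by
    the selection-recovery experiments.  Returns (FeatureTable, informative
    feature names).
    """
    from .io_formats import FeatureTable

    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    X[n_per_class:, :n_informative] += effect
    names = [f"feat_{j:03d}" for j in range(n_features)]
    ids = [f"s{i:03d}" for i in range(n)]
    table = FeatureTable.from_records(ids, labels, {nm: X[:, j] for j, nm in enumerate(names)})
    return table, names[:n_informative]
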