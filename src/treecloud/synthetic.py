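"""Synthetic two-species multispectral scene generator.

Stands in for 4-band satellite imagery (blue/green/red/NIR, reflectance in
(0, 1]) over a mixed deciduous forest with two species classes.  Two
"phenological presets" are shipped:

* ``autumn`` — leaf-on canopies; the classes differ mostly in the NIR band
  with a standardized mean separation of about 1.5 pooled standard
  deviations.
* ``winter`` — defoliating canopies; class separation is concentrated in
  the red and NIR bands (about 2.5 and 3.0 standardized units), making the
  classes markedly easier to tell apart than in autumn.

Each species also carries a spatial-texture correlation length (in pixels)
so that rasters exhibit class-specific autocorrelation and co-occurrence
texture features can discriminate where single-pixel spectra cannot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

N_BANDS = 4
BAND_COLUMNS = ["b1", "b2", "b3", "b4"]


class ConfigurationError(ValueError):
    """Raised for invalid generator or model configuration."""


@dataclass(frozen=True)
class SpeciesSpec:
    """Class-conditional reflectance model for one species.

    Parameters
    ----------
    name:
        Species identifier (used as the class label).
    band_means, band_sds:
        Per-band mean and standard deviation of reflectance.  Draws are
        truncated to (0, 1].
    texture_scale:
        Correlation length (Gaussian kernel sigma, in pixels) of the
        within-class spatial variation on rasters.  0 means white noise.
    """

    name: str
    band_means: tuple[float, float, float, float]
    band_sds: tuple[float, float, float, float]
    texture_scale: float = 0.0

    def __post_init__(self) -> None:
        if len(self.band_means) != N_BANDS or len(self.band_sds) != N_BANDS:
            raise ConfigurationError("exactly 4 band means and sds required")
        if any(sd < 0 for sd in self.band_sds):
            raise ConfigurationError("band_sds must be non-negative")
        if not all(0 < m < 1 for m in self.band_means):
            raise ConfigurationError("band_means must lie in (0, 1)")
        if self.texture_scale < 0:
            raise ConfigurationError("texture_scale must be >= 0")


@dataclass(frozen=True)
class PhasePreset:
    """A phenological phase: a pair of species reflectance models."""

    phase_name: str
    species_specs: tuple[SpeciesSpec, SpeciesSpec]

    def __post_init__(self) -> None:
        if len(self.species_specs) != 2:
            raise ConfigurationError("a preset holds exactly two species")
        a, b = self.species_specs
        if a.name == b.name:
            raise ConfigurationError("species names must differ")

    @property
    def species_names(self) -> tuple[str, str]:
        return tuple(s.name for s in self.species_specs)


# Default presets.  Band order: blue, green, red, NIR.  Standardized band-4
# separation is 1.5 (autumn) and 3.0 (winter); winter adds a 2.5-sd red-band
# separation, reflecting exposed trunk/branch signal after leaf fall.
# Texture scales differ by class (stand-scale patchiness: crown size and
# canopy density); both are several pixels so that window statistics cannot
# average the within-class variability away, keeping the class signal
# predominantly spectral.
AUTUMN = PhasePreset(
    "autumn",
    (
        SpeciesSpec("Q", (0.080, 0.100, 0.070, 0.350), (0.02,) * 4, texture_scale=8.0),
        SpeciesSpec("R", (0.085, 0.105, 0.085, 0.320), (0.02,) * 4, texture_scale=4.0),
    ),
)
WINTER = PhasePreset(
    "winter",
    (
        SpeciesSpec("Q", (0.120, 0.140, 0.160, 0.280), (0.02,) * 4, texture_scale=8.0),
        SpeciesSpec("R", (0.125, 0.150, 0.210, 0.220), (0.02,) * 4, texture_scale=4.0),
    ),
)
PRESETS: dict[str, PhasePreset] = {"autumn": AUTUMN, "winter": WINTER}


def get_preset(name: str) -> PhasePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Pixel-sample generation
# ---------------------------------------------------------------------------

_EPS = 1e-9  # open lower bound of the reflectance interval


def _truncated_band(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Draw n reflectances from Normal(mean, sd) truncated to (0, 1]."""
    if sd == 0:
        return np.full(n, mean)
    a, b = (_EPS - mean) / sd, (1.0 - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.rvs(size=n, random_state=rng)


def gen_pixel_samples(
    preset: PhasePreset, n_per_class: int, seed: int
) -> pd.DataFrame:
    """Draw labeled 4-band pixel samples from the class-conditional model.

    Returns a DataFrame with columns ``label, b1, b2, b3, b4``, all samples
    of the first species followed by all of the second.  Reproducible for a
    fixed seed.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for spec in preset.species_specs:
        bands = np.column_stack(
            [
                _truncated_band(rng, m, sd, n_per_class)
                for m, sd in zip(spec.band_means, spec.band_sds)
            ]
        )
        df = pd.DataFrame(bands, columns=BAND_COLUMNS)
        df.insert(0, "label", spec.name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Raster generation
# ---------------------------------------------------------------------------


@dataclass
class LabeledRaster:
    """An H×W×4 reflectance grid plus an H×W species-label mask."""

    bands: np.ndarray  # float, H x W x 4, values in (0, 1]
    labels: np.ndarray  # object/str, H x W
    class_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.bands.shape[:2] != self.labels.shape:
            raise ConfigurationError("bands and labels shapes disagree")
        if self.bands.shape[2] != N_BANDS:
            raise ConfigurationError("raster must carry 4 bands")


def _correlated_noise(
    rng: np.random.Generator, shape: tuple[int, int], scale: float
) -> np.ndarray:
    """Unit-variance Gaussian field with correlation length ``scale`` px.

    Gaussian-kernel smoothing of white noise, renormalized to unit variance
    so the marginal per-pixel sd is unaffected by the correlation length.
    """
    z = rng.standard_normal(shape)
    if scale <= 0:
        return z
    sm = ndimage.gaussian_filter(z, sigma=scale, mode="wrap")
    sd = sm.std()
    if sd < 1e-12:  # pathological: kernel wider than the raster
        return np.zeros(shape)
    return sm / sd


def gen_labeled_raster(
    preset: PhasePreset, height: int, width: int, seed: int, patch_cols: int = 2
) -> LabeledRaster:
    """Generate a raster of contiguous single-species patches.

    The scene is split into ``patch_cols`` vertical strips assigned to the
    two species alternately; within a patch every band equals the class
    mean plus spatially smoothed noise with the class's ``texture_scale``,
    clipped to (0, 1].
    """
    if height < 8 or width < 8:
        raise ConfigurationError("raster must be at least 8x8")
    if patch_cols < 2:
        raise ConfigurationError("need at least 2 patches to place 2 species")
    rng = np.random.default_rng(seed)
    labels = np.empty((height, width), dtype=object)
    bands = np.empty((height, width, N_BANDS))
    edges = np.linspace(0, width, patch_cols + 1).astype(int)
    # Per-class full-size noise fields (one per band) keep the spatial
    # correlation structure intact across patch boundaries of the same class.
    fields = {
        spec.name: np.stack(
            [
                _correlated_noise(rng, (height, width), spec.texture_scale)
                for _ in range(N_BANDS)
            ],
            axis=-1,
        )
        for spec in preset.species_specs
    }
    for p in range(patch_cols):
        spec = preset.species_specs[p % 2]
        sl = np.s_[:, edges[p] : edges[p + 1]]
        labels[sl] = spec.name
        means = np.asarray(spec.band_means)
        sds = np.asarray(spec.band_sds)
        bands[sl] = means + fields[spec.name][sl] * sds
    np.clip(bands, _EPS, 1.0, out=bands)
    return LabeledRaster(bands, labels, class_names=preset.species_names)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_samples_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"label", *BAND_COLUMNS} - set(df.columns)
    if missing:
        raise ConfigurationError(f"sample table missing columns {sorted(missing)}")
    return df


def write_raster_tiff(raster: LabeledRaster, bands_path, labels_path) -> None:
    """Write reflectance as 4-band float32 TIFF, labels as uint8 TIFF."""
    import tifffile

    # band-first layout, one page per band
    tifffile.imwrite(
        bands_path,
        np.moveaxis(raster.bands, -1, 0).astype(np.float32),
        photometric="minisblack",
    )
    names = sorted(set(raster.labels.ravel().tolist()))
    code = {n: i for i, n in enumerate(names)}
    coded = np.vectorize(code.get)(raster.labels).astype(np.uint8)
    tifffile.imwrite(labels_path, coded, description=",".join(names))


def read_raster_tiff(bands_path, labels_path) -> LabeledRaster:
    import tifffile

    bands = np.asarray(tifffile.imread(bands_path), dtype=float)
    if bands.ndim == 3 and bands.shape[0] == N_BANDS and bands.shape[2] != N_BANDS:
        bands = np.moveaxis(bands, 0, -1)  # accept band-first layout
    with tifffile.TiffFile(labels_path) as tf:
        coded = tf.asarray()
        desc = tf.pages[0].description or ""
    names = desc.split(",") if desc else [str(v) for v in np.unique(coded)]
    labels = np.asarray(names, dtype=object)[coded]
    return LabeledRaster(bands, labels, class_names=tuple(names))


def raster_to_samples(raster: LabeledRaster) -> pd.DataFrame:
    """Flatten a raster row-major into a labeled pixel-sample table."""
    h, w, _ = raster.bands.shape
    df = pd.DataFrame(raster.bands.reshape(h * w, N_BANDS), columns=BAND_COLUMNS)
    df.insert(0, "label", raster.labels.ravel())
    return df
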