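"""Ground-truthed synthetic MSI datacubes emulating bronchoscopic biopsies.

A simulated section is a small raster (25 um pixels) containing three tissue
regions — epithelium, cellular stroma and fibrous stroma — over a background
that carries no spectrum (processed-mode semantics).  Each region has a
lipid-class percentage profile; per-pixel spectra are drawn by

* sampling species fractions within each class from a Dirichlet centered on
  the region profile (keeps compositions valid),
* emitting each species at its theoretical adduct m/z perturbed by Gaussian
  ppm jitter,
* scaling all intensities by a log-normal per-pixel TIC factor, and
* adding a Poisson number of low-intensity noise peaks at uniform m/z.

Between-subject (section-to-section) variation is Gaussian on the logit of
the species fractions, renormalized per class.

Epithelial profiles encode the reported group percentages for the bronchial
biopsy cohorts (control, smoker, non-tumor, tumor, COPD); species that were
not reported individually receive the residual share of their class and are
flagged as assumed.  Stromal profiles are derived from the epithelial ones by
the reported qualitative rules: arachidonic-acid carriers (PI 38:4, PE 38:4)
at least 2-fold enriched, DHA carriers (PE 38:6, PE 40:6, PE P 38:6,
PE P 40:6, PS 40:6) depleted by 30-90%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .lipid_db import LipidClass, PanelEntry, default_panel
from .msi_io import Datacube, PixelSpectrum

__all__ = [
    "BACKGROUND",
    "REGION_LABELS",
    "TissuePhantom",
    "RegionProfile",
    "AcquisitionParams",
    "make_phantom",
    "default_group_profiles",
    "draw_section_profiles",
    "sample_pixel_spectrum",
    "simulate_section",
    "simulate_cohort",
    "SectionGroundTruth",
    "DEFAULT_COHORT_SIZES",
]

BACKGROUND = 0
REGION_LABELS: dict[int, str] = {1: "epithelium", 2: "cellular_stroma", 3: "fibrous_stroma"}
_LABEL_BY_NAME = {v: k for k, v in REGION_LABELS.items()}

GROUPS = ("control", "smoker", "non_tumor", "tumor", "copd")

#: Cohort sizes (sections per group) of the bronchial biopsy study.
DEFAULT_COHORT_SIZES: dict[str, int] = {
    "tumor": 5,
    "non_tumor": 5,
    "copd": 4,
    "smoker": 5,
    "control": 4,
}


@dataclass
class TissuePhantom:
    """Integer label image of one simulated biopsy section."""

    label_grid: np.ndarray  # rows x cols, labels {0 bg, 1 E, 2 CS, 3 FS}
    pixel_size: float = 25.0

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid, dtype=np.int64)
        if self.label_grid.ndim != 2 or min(self.label_grid.shape) < 16:
            raise ValueError("phantom grid must be 2-D and at least 16x16")
        bad = set(np.unique(self.label_grid)) - ({BACKGROUND} | set(REGION_LABELS))
        if bad:
            raise ValueError(f"unknown labels in phantom: {sorted(bad)}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.label_grid.shape)  # type: ignore[return-value]

    @property
    def n_tissue_pixels(self) -> int:
        return int(np.count_nonzero(self.label_grid))

    def region_coords(self, label: int) -> list[tuple[int, int]]:
        rr, cc = np.nonzero(self.label_grid == label)
        return list(zip(rr.tolist(), cc.tolist()))


def make_phantom(rows: int, cols: int, layout: str = "banded", mask: np.ndarray | None = None,
                 pixel_size: float = 25.0) -> TissuePhantom:
    """Deterministic phantom geometry.

    ``banded`` stacks an epithelial band over cellular stroma over fibrous
    stroma, with a background strip where the section does not reach the
    raster edge; ``nested`` wraps epithelium around cellular stroma around a
    fibrous core; ``from_mask`` adopts a provided label image.
    """
    if rows < 16 or cols < 16:
        raise ValueError("phantom dims must be at least 16x16")
    grid = np.zeros((rows, cols), dtype=np.int64)
    if layout == "from_mask":
        if mask is None:
            raise ValueError("from_mask layout requires a mask")
        return TissuePhantom(np.asarray(mask), pixel_size)
    if layout == "banded":
        n_bg = round(0.1 * rows)
        tissue = rows - n_bg
        n_e = round(0.25 * tissue)
        n_cs = round(0.40 * tissue)
        grid[:n_e, :] = 1
        grid[n_e:n_e + n_cs, :] = 2
        grid[n_e + n_cs:tissue, :] = 3
    elif layout == "nested":
        w = max(2, rows // 16)
        t = max(2, rows // 8)
        grid[w:rows - w, w:cols - w] = 1
        grid[w + t:rows - w - t, w + t:cols - w - t] = 2
        grid[w + 2 * t:rows - w - 2 * t, w + 2 * t:cols - w - 2 * t] = 3
    else:
        raise ValueError(f"unknown layout {layout!r}")
    phantom = TissuePhantom(grid, pixel_size)
    n = phantom.n_tissue_pixels
    for label in REGION_LABELS:
        if np.count_nonzero(grid == label) < 0.10 * n:
            raise AssertionError("layout produced a region below 10% of tissue")
    return phantom


# -- region profiles ---------------------------------------------------------


@dataclass
class RegionProfile:
    """Ground-truth species percentages (of class total) for one region.

    ``percentages`` maps lipid class -> {"C:D": percent}; within each class
    the values sum to 100.  ``class_weights`` give each class's relative share
    of the region's total signal.  ``assumed`` lists species whose value was
    not reported and fills the class residual.
    """

    percentages: dict[LipidClass, dict[str, float]]
    class_weights: dict[LipidClass, float]
    assumed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for cls, spp in self.percentages.items():
            total = sum(spp.values())
            if any(v < 0 for v in spp.values()):
                raise ValueError(f"negative percentage in {cls}")
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"{cls} percentages sum to {total}, not 100")

    def pct(self, cls: LipidClass, key: str) -> float:
        return self.percentages[cls][key.lstrip("d")]

    def species_intensity_shares(self, panel_keys: dict[LipidClass, list[str]]
                                 ) -> tuple[list[tuple[LipidClass, str]], np.ndarray]:
        """Flatten to (class, key) order with class_weight * fraction values."""
        ids, vals = [], []
        for cls, keys in panel_keys.items():
            w = self.class_weights.get(cls, 0.0)
            for k in keys:
                ids.append((cls, k))
                vals.append(w * self.percentages.get(cls, {}).get(k, 0.0) / 100.0)
        return ids, np.asarray(vals)


def _profile(pi, pe, pep, ps, sm, weights, assumed) -> RegionProfile:
    return RegionProfile(
        {LipidClass.PI: pi, LipidClass.PE: pe, LipidClass.PE_P: pep,
         LipidClass.PS: ps, LipidClass.SM: sm},
        weights, set(assumed),
    )


_EPI_WEIGHTS = {LipidClass.PE: 0.35, LipidClass.PI: 0.25, LipidClass.SM: 0.15,
                LipidClass.PS: 0.15, LipidClass.PE_P: 0.10}
_CS_WEIGHTS = {LipidClass.PE: 0.33, LipidClass.PI: 0.30, LipidClass.SM: 0.11,
               LipidClass.PS: 0.16, LipidClass.PE_P: 0.10}
_FS_WEIGHTS = {LipidClass.PE: 0.20, LipidClass.PI: 0.28, LipidClass.SM: 0.27,
               LipidClass.PS: 0.17, LipidClass.PE_P: 0.08}

# Epithelial profiles.  Reported values are carried verbatim; the remaining
# species of each class absorb the residual to 100 ("assumed").
_EPI_ASSUMED = {"PI 36:1", "PI 36:4", "PI 38:3", "PE 38:2", "PE 38:6", "PE 40:6",
                "PE P 34:1", "PE P 40:4", "PS 36:1", "PS 36:2",
                "SM d36:1", "SM d42:1", "SM d42:2"}

_EPITHELIUM: dict[str, RegionProfile] = {
    "non_tumor": _profile(
        pi={"32:0": 1.8, "34:1": 13.7, "34:2": 5.9, "36:1": 6.1, "36:2": 12.5,
            "36:4": 9.5, "38:3": 9.0, "38:4": 41.5},
        pe={"36:1": 31.0, "36:2": 18.8, "36:4": 1.3, "38:2": 15.0, "38:4": 14.5,
            "38:6": 11.0, "40:6": 8.4},
        pep={"34:1": 12.0, "36:1": 30.0, "38:4": 22.0, "38:6": 18.0, "40:4": 6.0,
             "40:6": 12.0},
        ps={"36:1": 26.0, "36:2": 18.0, "38:4": 30.0, "40:6": 26.0},
        sm={"34:1": 70.7, "36:1": 10.3, "42:1": 9.0, "42:2": 10.0},
        weights=_EPI_WEIGHTS, assumed=_EPI_ASSUMED,
    ),
    "tumor": _profile(
        pi={"32:0": 0.3, "34:1": 3.8, "34:2": 1.8, "36:1": 5.5, "36:2": 5.3,
            "36:4": 8.0, "38:3": 8.0, "38:4": 67.3},
        pe={"36:1": 25.9, "36:2": 16.1, "36:4": 2.2, "38:2": 13.0, "38:4": 27.7,
            "38:6": 8.6, "40:6": 6.5},
        pep={"34:1": 22.3, "36:1": 15.2, "38:4": 26.0, "38:6": 16.5, "40:4": 9.0,
             "40:6": 11.0},
        ps={"36:1": 24.5, "36:2": 18.0, "38:4": 44.7, "40:6": 12.8},
        sm={"34:1": 58.5, "36:1": 14.0, "42:1": 13.0, "42:2": 14.5},
        weights=_EPI_WEIGHTS, assumed=_EPI_ASSUMED,
    ),
    "control": _profile(
        pi={"32:0": 1.8, "34:1": 9.0, "34:2": 5.9, "36:1": 13.3, "36:2": 12.5,
            "36:4": 9.5, "38:3": 8.0, "38:4": 40.0},
        pe={"36:1": 30.0, "36:2": 18.5, "36:4": 1.3, "38:2": 14.0, "38:4": 15.2,
            "38:6": 12.0, "40:6": 9.0},
        pep={"34:1": 11.0, "36:1": 31.0, "38:4": 22.0, "38:6": 18.0, "40:4": 5.0,
             "40:6": 13.0},
        ps={"36:1": 26.0, "36:2": 19.0, "38:4": 28.0, "40:6": 27.0},
        sm={"34:1": 72.0, "36:1": 10.0, "42:1": 8.5, "42:2": 9.5},
        weights=_EPI_WEIGHTS, assumed=_EPI_ASSUMED,
    ),
    "smoker": _profile(
        pi={"32:0": 1.8, "34:1": 7.2, "34:2": 5.5, "36:1": 12.0, "36:2": 12.0,
            "36:4": 9.5, "38:3": 8.0, "38:4": 44.0},
        pe={"36:1": 29.5, "36:2": 18.0, "36:4": 1.4, "38:2": 13.1, "38:4": 17.0,
            "38:6": 12.0, "40:6": 9.0},
        pep={"34:1": 11.0, "36:1": 30.0, "38:4": 23.0, "38:6": 18.0, "40:4": 5.0,
             "40:6": 13.0},
        ps={"36:1": 27.0, "36:2": 19.0, "38:4": 27.0, "40:6": 27.0},
        sm={"34:1": 71.0, "36:1": 10.0, "42:1": 9.0, "42:2": 10.0},
        weights=_EPI_WEIGHTS, assumed=_EPI_ASSUMED,
    ),
    "copd": _profile(
        pi={"32:0": 1.8, "34:1": 9.0, "34:2": 5.9, "36:1": 9.5, "36:2": 8.4,
            "36:4": 9.5, "38:3": 15.9, "38:4": 40.0},
        pe={"36:1": 31.8, "36:2": 14.2, "36:4": 1.3, "38:2": 10.4, "38:4": 21.3,
            "38:6": 12.0, "40:6": 9.0},
        pep={"34:1": 11.0, "36:1": 30.0, "38:4": 24.0, "38:6": 17.5, "40:4": 5.0,
             "40:6": 12.5},
        ps={"36:1": 33.0, "36:2": 22.6, "38:4": 15.4, "40:6": 29.0},
        sm={"34:1": 70.0, "36:1": 10.5, "42:1": 9.5, "42:2": 10.0},
        weights=_EPI_WEIGHTS, assumed=_EPI_ASSUMED,
    ),
}

#: DHA (22:6) carriers depleted in stroma relative to epithelium.
_DHA_SPECIES = {(LipidClass.PE, "38:6"), (LipidClass.PE, "40:6"),
                (LipidClass.PE_P, "38:6"), (LipidClass.PE_P, "40:6"),
                (LipidClass.PS, "40:6")}


def _stromal_from_epithelial(epi: RegionProfile, *, pi384_factor: float, pi384_cap: float,
                             pe384_factor: float, pe384_cap: float, dha_reduction: float,
                             pe361_factor: float, weights: dict[LipidClass, float],
                             sm_longchain_shift: float = 0.0) -> RegionProfile:
    """Apply the stromal transformation rules and renormalize each class.

    ``sm_longchain_shift`` moves that many percentage points of SM from the
    d34:1 species to the very-long-chain d42:1/d42:2 species, giving the
    collagen-rich, cell-poor fibrous stroma a distinct sphingomyelin
    chain-length signature."""
    out: dict[LipidClass, dict[str, float]] = {}
    fixed_rules = {
        (LipidClass.PI, "38:4"): lambda v: min(pi384_cap, pi384_factor * v),
        (LipidClass.PE, "38:4"): lambda v: min(pe384_cap, pe384_factor * v),
        (LipidClass.PE, "36:1"): lambda v: pe361_factor * v,
    }
    for cls, spp in epi.percentages.items():
        fixed: dict[str, float] = {}
        for key, val in spp.items():
            if (cls, key) in _DHA_SPECIES:
                fixed[key] = (1.0 - dha_reduction) * val
            elif (cls, key) in fixed_rules:
                fixed[key] = fixed_rules[(cls, key)](val)
        free = {k: v for k, v in spp.items() if k not in fixed}
        residual = 100.0 - sum(fixed.values())
        if residual <= 0 or not free:
            raise ValueError("stromal transformation left no residual mass")
        scale = residual / sum(free.values())
        merged = {**fixed, **{k: v * scale for k, v in free.items()}}
        # close to exactly 100 against float drift
        total = sum(merged.values())
        out[cls] = {k: v * 100.0 / total for k, v in merged.items()}
    if sm_longchain_shift > 0:
        sm = out[LipidClass.SM]
        shift = min(sm_longchain_shift, 0.5 * sm["34:1"])
        sm["34:1"] -= shift
        sm["42:1"] += 0.5 * shift
        sm["42:2"] += 0.5 * shift
    return RegionProfile(out, dict(weights), set(epi.assumed))


def default_group_profiles(group: str) -> dict[str, RegionProfile]:
    """Region profiles (epithelium / cellular_stroma / fibrous_stroma) for one
    study group."""
    if group not in _EPITHELIUM:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    epi = _EPITHELIUM[group]
    cs = _stromal_from_epithelial(
        epi, pi384_factor=2.15, pi384_cap=85.0, pe384_factor=2.15, pe384_cap=45.0,
        dha_reduction=0.60, pe361_factor=0.75, weights=_CS_WEIGHTS)
    fs = _stromal_from_epithelial(
        epi, pi384_factor=2.05, pi384_cap=82.0, pe384_factor=2.05, pe384_cap=42.0,
        dha_reduction=0.50, pe361_factor=0.50, weights=_FS_WEIGHTS,
        sm_longchain_shift=20.0)
    return {"epithelium": epi, "cellular_stroma": cs, "fibrous_stroma": fs}


# -- acquisition model -------------------------------------------------------


@dataclass
class AcquisitionParams:
    """Noise model of one simulated acquisition.

    The jitter default (2 ppm) keeps emitted peaks inside the instrument's
    typical <3 ppm accuracy; the hard validity bound is the 9 ppm assignment
    limit.
    """

    mz_range: tuple[float, float] = (550.0, 1000.0)
    ppm_jitter_sd: float = 2.0
    tic_lognormal_sd: float = 0.3
    pixel_dirichlet_concentration: float = 200.0
    noise_peak_rate: float = 10.0
    noise_intensity_fraction: float = 0.02
    base_intensity: float = 1e4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.ppm_jitter_sd < 9):
            raise ValueError("ppm_jitter_sd must be in [0, 9)")
        lo, hi = self.mz_range
        if not (550.0 <= lo < hi <= 1000.0):
            raise ValueError("mz_range must lie within [550, 1000]")

    @classmethod
    def zero_noise(cls, **kw) -> "AcquisitionParams":
        return cls(ppm_jitter_sd=0.0, tic_lognormal_sd=0.0,
                   pixel_dirichlet_concentration=math.inf,
                   noise_peak_rate=0.0, **kw)


def _panel_keys(panel: list[PanelEntry]) -> dict[LipidClass, list[str]]:
    keys: dict[LipidClass, list[str]] = {}
    for e in panel:
        keys.setdefault(e.species.lipid_class, []).append(
            f"{e.species.total_carbons}:{e.species.double_bonds}")
    return keys


def _sample_class_fractions(fracs: np.ndarray, concentration: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw centered on ``fracs`` (sum 1); infinite concentration
    returns the center exactly.  Zero entries stay exactly zero."""
    if math.isinf(concentration):
        return fracs
    g = np.where(fracs > 0, rng.gamma(np.maximum(fracs * concentration, 1e-12)), 0.0)
    total = g.sum()
    return g / total if total > 0 else fracs


def sample_pixel_spectrum(profile: RegionProfile, params: AcquisitionParams,
                          rng: np.random.Generator, coord: tuple[int, int] = (0, 0),
                          panel: list[PanelEntry] | None = None) -> PixelSpectrum:
    """Draw one pixel spectrum from a region profile."""
    if panel is None:
        panel = default_panel()
    keys = _panel_keys(panel)
    mz_theo = {(e.species.lipid_class,
                f"{e.species.total_carbons}:{e.species.double_bonds}"): e.mz
               for e in panel}
    return _sample_pixel(profile, params, rng, coord, keys, mz_theo)


@dataclass
class SectionGroundTruth:
    """Everything needed to score downstream recovery on one section."""

    phantom: TissuePhantom
    group: str
    profiles: dict[str, RegionProfile]  # region name -> profile
    species_mz: dict[str, float]  # species name -> theoretical adduct m/z
    seed: int | None
    section_id: str = "section0"

    def save(self, directory: str | Path) -> None:
        """Serialize as JSON (profiles, m/z table) plus a TSV label grid."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / f"{self.section_id}_labels.tsv",
                   self.phantom.label_grid, fmt="%d", delimiter="\t")
        doc = {
            "group": self.group,
            "seed": self.seed,
            "section_id": self.section_id,
            "pixel_size": self.phantom.pixel_size,
            "species_mz": self.species_mz,
            "profiles": {
                region: {
                    "class_weights": {c.value: w for c, w in p.class_weights.items()},
                    "percentages": {c.value: dict(sorted(s.items()))
                                    for c, s in p.percentages.items()},
                    "assumed": sorted(p.assumed),
                }
                for region, p in self.profiles.items()
            },
        }
        (directory / f"{self.section_id}_truth.json").write_text(
            json.dumps(doc, indent=1, sort_keys=True))


def simulate_section(phantom: TissuePhantom, group_profiles: dict[str, RegionProfile],
                     params: AcquisitionParams | None = None,
                     seed: int | None = None,
                     panel: list[PanelEntry] | None = None,
                     group: str = "custom",
                     section_id: str = "section0") -> tuple[Datacube, SectionGroundTruth]:
    """Simulate one section: one spectrum per non-background pixel."""
    params = params or AcquisitionParams()
    if panel is None:
        panel = default_panel()
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    keys = _panel_keys(panel)
    mz_theo = {(e.species.lipid_class,
                f"{e.species.total_carbons}:{e.species.double_bonds}"): e.mz
               for e in panel}
    spectra: list[PixelSpectrum] = []
    for label, region in REGION_LABELS.items():
        coords = phantom.region_coords(label)
        if not coords:
            continue
        if region not in group_profiles:
            raise ValueError(f"no profile supplied for region {region!r}")
        profile = group_profiles[region]
        for coord in coords:
            spectra.append(_sample_pixel(profile, params, rng, coord, keys, mz_theo))
    spectra.sort(key=lambda s: s.coord)
    cube = Datacube(spectra, phantom.grid_shape, pixel_size=phantom.pixel_size)
    truth = SectionGroundTruth(
        phantom=phantom, group=group, profiles=dict(group_profiles),
        species_mz={e.species.name: e.mz for e in panel}, seed=seed,
        section_id=section_id)
    return cube, truth


def _sample_pixel(profile, params, rng, coord, keys, mz_theo) -> PixelSpectrum:
    """Same model as :func:`sample_pixel_spectrum` with precomputed tables."""
    intens = []
    ids = []
    for cls, cls_keys in keys.items():
        w = profile.class_weights.get(cls, 0.0)
        center = np.array([profile.percentages.get(cls, {}).get(k, 0.0) / 100.0
                           for k in cls_keys])
        fr = _sample_class_fractions(center, params.pixel_dirichlet_concentration, rng)
        intens.append(w * fr)
        ids.extend((cls, k) for k in cls_keys)
    intensity = np.concatenate(intens) * params.base_intensity
    if params.tic_lognormal_sd > 0:
        intensity = intensity * math.exp(rng.normal(0.0, params.tic_lognormal_sd))
    mz = np.array([mz_theo[i] for i in ids])
    if params.ppm_jitter_sd > 0:
        mz = mz * (1.0 + rng.normal(0.0, params.ppm_jitter_sd, mz.size) * 1e-6)
    present = intensity > 0
    mz, intensity = mz[present], intensity[present]
    n_noise = rng.poisson(params.noise_peak_rate) if params.noise_peak_rate > 0 else 0
    if n_noise:
        lo, hi = params.mz_range
        noise_mz = rng.uniform(lo, hi, n_noise)
        noise_int = (params.noise_intensity_fraction * float(np.median(intensity))
                     * rng.exponential(1.0, n_noise))
        mz = np.concatenate([mz, noise_mz])
        intensity = np.concatenate([intensity, noise_int])
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    dup = np.flatnonzero(np.diff(mz) <= 0)
    for i in dup:
        mz[i + 1] = np.nextafter(mz[i], np.inf)
    return PixelSpectrum(mz, intensity, coord)


def _logit_jitter(profile: RegionProfile, sd: float, rng: np.random.Generator
                  ) -> RegionProfile:
    """Between-subject variation: Gaussian on logit fractions, renormalized."""
    if sd == 0:
        return profile
    new: dict[LipidClass, dict[str, float]] = {}
    for cls, spp in profile.percentages.items():
        keys = list(spp)
        p = np.array([spp[k] / 100.0 for k in keys])
        pos = p > 0
        logit = np.log(p[pos] / (1.0 - p[pos]))
        logit = logit + rng.normal(0.0, sd, logit.size)
        q = 1.0 / (1.0 + np.exp(-logit))
        out = np.zeros_like(p)
        out[pos] = q / q.sum()
        new[cls] = {k: 100.0 * v for k, v in zip(keys, out)}
    return RegionProfile(new, dict(profile.class_weights), set(profile.assumed))


def draw_section_profiles(group_profiles: dict[str, RegionProfile], sd: float,
                          rng: np.random.Generator) -> dict[str, RegionProfile]:
    """One subject's region profiles, jittered around the group defaults."""
    return {region: _logit_jitter(p, sd, rng) for region, p in group_profiles.items()}


def simulate_cohort(groups: dict[str, int] | None = None, *,
                    rows: int = 64, cols: int = 64, layout: str = "banded",
                    params: AcquisitionParams | None = None,
                    master_seed: int = 0,
                    between_subject_sd: float = 0.06,
                    panel: list[PanelEntry] | None = None
                    ) -> list[tuple[Datacube, SectionGroundTruth]]:
    """Simulate a multi-group cohort with per-section seeds derived
    deterministically from ``master_seed``."""
    groups = dict(groups) if groups is not None else dict(DEFAULT_COHORT_SIZES)
    for g, n in groups.items():
        if n <= 0:
            raise ValueError(f"section count for {g!r} must be positive")
    params = params or AcquisitionParams()
    phantom = make_phantom(rows, cols, layout)
    master = np.random.default_rng(master_seed)
    sections = []
    for group in groups:  # insertion order: deterministic
        base = default_group_profiles(group)
        for i in range(groups[group]):
            section_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(section_seed)
            profiles = draw_section_profiles(base, between_subject_sd, rng)
            cube, truth = simulate_section(
                phantom, profiles, replace(params, seed=None), seed=section_seed,
                panel=panel, group=group, section_id=f"{group}_{i}")
            sections.append((cube, truth))
    return sections
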