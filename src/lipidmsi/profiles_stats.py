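"""Feature annotation, lipid-class percentage profiles and group statistics.

A feature is annotated by the panel entry minimizing the absolute ppm error,

    ppm = (observed - theoretical) / theoretical * 1e6,

accepted when |ppm| is below the mass-accuracy bound (9 ppm).  Plasmalogen /
alkyl-ether isobars (PE P c:d vs PE O c:(d+1)) are resolved to PE P, and the
suppressed alternative is recorded in an isobar ledger.

The per-species percentage within its class is

    species_i% = I_i / sum_j I_j * 100

with intensities summed over the contributing pixels (intensity-weighted),
so the profile is invariant to rescaling a whole class.  Section-level
profiles aggregate into group mean +/- SEM (n = sections, the biological
replicate) and groups are compared species-wise by unpaired t-tests with the
conventional significance tiers (p <= 0.05 / 0.01 / 0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .lipid_db import LipidClass, PanelEntry
from .msi_io import FeatureMatrix

__all__ = [
    "AnnotationMatch",
    "Annotations",
    "ClassProfile",
    "GroupComparison",
    "annotate_features",
    "class_percentages",
    "profiles_for_tissues",
    "aggregate_group",
    "percent_change",
    "compare_groups",
    "stars_for",
    "comparisons_to_tsv",
]

MAX_PPM_DEFAULT = 9.0


@dataclass(frozen=True)
class AnnotationMatch:
    feature_index: int
    feature_mz: float
    species_name: str | None
    lipid_class: LipidClass | None
    species_key: str | None  # "C:D"
    theoretical_mz: float | None
    ppm_error: float | None
    accepted: bool


@dataclass
class Annotations:
    matches: list[AnnotationMatch]
    #: (feature_index, assigned species, suppressed isobaric species)
    isobar_ledger: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def accepted(self) -> list[AnnotationMatch]:
        return [m for m in self.matches if m.accepted]

    def species_features(self) -> dict[tuple[LipidClass, str], list[int]]:
        """Feature indices per annotated species (satellite features of the
        same species are pooled)."""
        out: dict[tuple[LipidClass, str], list[int]] = {}
        for m in self.accepted:
            out.setdefault((m.lipid_class, m.species_key), []).append(m.feature_index)
        return out


def annotate_features(matrix: FeatureMatrix, panel: list[PanelEntry],
                      max_ppm: float = MAX_PPM_DEFAULT) -> Annotations:
    """Match each feature to the closest panel entry within ``max_ppm``."""
    if not panel:
        raise ValueError("empty panel")
    theo = np.array([e.mz for e in panel])
    matches = []
    ledger = []
    for i, mz in enumerate(matrix.mz_axis):
        ppm_all = (mz - theo) / theo * 1e6
        j = int(np.argmin(np.abs(ppm_all)))
        ppm = float(ppm_all[j])
        if abs(ppm) < max_ppm:
            e = panel[j]
            key = f"{e.species.total_carbons}:{e.species.double_bonds}"
            matches.append(AnnotationMatch(i, float(mz), e.species.name,
                                           e.species.lipid_class, key, e.mz, ppm, True))
            if e.isobar_alternative is not None:
                ledger.append((i, e.species.name, e.isobar_alternative))
        else:
            matches.append(AnnotationMatch(i, float(mz), None, None, None, None,
                                           ppm, False))
    return Annotations(matches, ledger)


@dataclass
class ClassProfile:
    """Per-class species percentages for one segment/tissue."""

    label: str
    percentages: dict[LipidClass, dict[str, float]]
    n_pixels: int
    missing: dict[LipidClass, list[str]] = field(default_factory=dict)

    def pct(self, cls: LipidClass, key: str) -> float:
        return self.percentages[cls][key.lstrip("d")]


def class_percentages(matrix: FeatureMatrix, annotations: Annotations,
                      pixel_subset: np.ndarray | list[int], label: str = ""
                      ) -> ClassProfile:
    """Species percentages of class totals over a pixel subset.

    Species intensities are summed over the subset's pixels; classes with zero
    total are reported under ``missing`` rather than as 0/0.
    """
    subset = np.asarray(pixel_subset)
    if subset.dtype == bool:
        subset = np.flatnonzero(subset)
    if subset.size == 0:
        raise ValueError("empty pixel subset")
    from scipy import sparse

    sums: dict[LipidClass, dict[str, float]] = {}
    for (cls, key), feats in annotations.species_features().items():
        if sparse.issparse(matrix.values):
            total = float(matrix.values[subset][:, feats].sum())
        else:
            total = float(matrix.values[np.ix_(subset, feats)].sum())
        sums.setdefault(cls, {})[key] = sums.get(cls, {}).get(key, 0.0) + total
    percentages: dict[LipidClass, dict[str, float]] = {}
    missing: dict[LipidClass, list[str]] = {}
    for cls, spp in sums.items():
        class_total = sum(spp.values())
        if class_total <= 0:
            missing[cls] = sorted(spp)
            continue
        percentages[cls] = {k: v / class_total * 100.0 for k, v in spp.items()}
    return ClassProfile(label, percentages, int(subset.size), missing)


def profiles_for_tissues(matrix: FeatureMatrix, annotations: Annotations,
                         tissue_labels: np.ndarray,
                         names: dict[int, str]) -> dict[str, ClassProfile]:
    """One ClassProfile per tissue label (per-pixel labels aligned with the
    matrix rows)."""
    out = {}
    for lab, name in names.items():
        subset = np.flatnonzero(np.asarray(tissue_labels) == lab)
        if subset.size:
            out[name] = class_percentages(matrix, annotations, subset, label=name)
    return out


def aggregate_group(profiles: list[ClassProfile]
                    ) -> dict[tuple[LipidClass, str], tuple[float, float | None]]:
    """Average section-level percentages into group mean +/- SEM.

    SEM = sd / sqrt(n) with n = number of sections carrying the species;
    undefined (None) when n < 2.
    """
    values: dict[tuple[LipidClass, str], list[float]] = {}
    for p in profiles:
        for cls, spp in p.percentages.items():
            for key, v in spp.items():
                values.setdefault((cls, key), []).append(v)
    out = {}
    for sp, vals in values.items():
        arr = np.asarray(vals)
        mean = float(arr.mean())
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size >= 2 else None
        out[sp] = (mean, sem)
    return out


def percent_change(mean_a: float, mean_b: float) -> float:
    """Relative change from A to B in percent, to one decimal."""
    if mean_a == 0:
        raise ValueError("percent change undefined for zero baseline")
    return round((mean_b - mean_a) / mean_a * 100.0, 1)


def stars_for(p_value: float) -> str:
    if p_value <= 0.001:
        return "***"
    if p_value <= 0.01:
        return "**"
    if p_value <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    species: str
    lipid_class: LipidClass
    species_key: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float | None
    sem_b: float | None
    percent_change: float | None
    t_statistic: float
    p_value: float
    stars: str
    p_adjusted: float | None = None


def compare_groups(profiles_a: list[ClassProfile], profiles_b: list[ClassProfile],
                   name_a: str = "A", name_b: str = "B", *, welch: bool = False,
                   fdr: bool = False) -> list[GroupComparison]:
    """Species-wise unpaired t-tests between two groups of sections.

    Pooled-variance by default; Welch via ``welch=True``.  Raw p-values by
    default; ``fdr=True`` adds Benjamini-Hochberg adjusted p-values without
    changing the star tiers (which follow the raw values).
    """
    agg_a = aggregate_group(profiles_a)
    agg_b = aggregate_group(profiles_b)
    per_species_a: dict[tuple[LipidClass, str], list[float]] = {}
    per_species_b: dict[tuple[LipidClass, str], list[float]] = {}
    for profiles, store in ((profiles_a, per_species_a), (profiles_b, per_species_b)):
        for p in profiles:
            for cls, spp in p.percentages.items():
                for key, v in spp.items():
                    store.setdefault((cls, key), []).append(v)
    results = []
    for sp in sorted(set(per_species_a) & set(per_species_b),
                     key=lambda s: (s[0].value, s[1])):
        a = np.asarray(per_species_a[sp])
        b = np.asarray(per_species_b[sp])
        if a.size < 2 or b.size < 2:
            continue
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
            t, p = float(t), float(p)
            if math.isnan(p):  # both degenerate but unequal: infinitely separated
                t, p = math.inf * np.sign(b.mean() - a.mean()), 0.0
        mean_a, sem_a = agg_a[sp]
        mean_b, sem_b = agg_b[sp]
        change = percent_change(mean_a, mean_b) if mean_a != 0 else None
        cls, key = sp
        name = f"SM d{key}" if cls is LipidClass.SM else f"{cls.value} {key}"
        results.append(GroupComparison(name, cls, key, name_a, name_b, mean_a,
                                       mean_b, sem_a, sem_b, change, t, p,
                                       stars_for(p)))
    if fdr and results:
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            prev = min(prev, results[i].p_value * m / (rank_pos + 1))
            adj[i] = prev
        results = [GroupComparison(**{**r.__dict__, "p_adjusted": float(adj[i])})
                   for i, r in enumerate(results)]
    return results


def comparisons_to_tsv(comparisons: list[GroupComparison], path: str | Path) -> None:
    df = pd.DataFrame([{
        "class": c.lipid_class.value,
        "species": c.species,
        "group_a": c.group_a,
        "group_b": c.group_b,
        "mean_a": c.mean_a,
        "mean_b": c.mean_b,
        "sem_a": c.sem_a,
        "sem_b": c.sem_b,
        "percent_change": c.percent_change,
        "t_statistic": c.t_statistic,
        "p_value": c.p_value,
        "p_adjusted": c.p_adjusted,
        "stars": c.stars,
    } for c in comparisons])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def profiles_to_tsv(profiles: dict[str, "ClassProfile"], path: str | Path,
                    section: str = "", group: str = "") -> None:
    """Tidy export: one row per (section, tissue, class, species)."""
    rows = []
    for tissue, prof in profiles.items():
        for cls, spp in prof.percentages.items():
            for key, v in sorted(spp.items()):
                rows.append({"section": section, "group": group, "tissue": tissue,
                             "class": cls.value, "species": key, "percent": v,
                             "n_pixels": prof.n_pixels})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
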