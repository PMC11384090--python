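"""End-to-end orchestration: subject analysis and cohort summaries.

``analyze_subject`` is the in-memory workhorse (used directly by tests and
the cohort runner); ``run_subject`` wraps it with file I/O — NIfTI in,
CSV/NIfTI/PNG/JSON out.  For every vertebra present in the label volume the
pipeline extracts the ROI, estimates the inclination, builds standardized
maps both without and (when requested) with inclination correction, and
derives volumetric and map-based statistics.  Keeping both variants in one
run makes the correction analysis a report, not a re-run.

Reports order vertebrae L5 → L1 (inferior to superior), the conventional
presentation for lumbar levels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import LabelError
from .inclination import estimate_roi_inclination, extract_vertebra_roi
from .standardize import (StandardizedMaps, TemplateGeometry,
                          build_standardized_maps)
from .stats_metrics import (bland_altman, compare_groups, confusion_metrics,
                            map_stats, volumetric_stats)
from .volume_io import (DEFAULT_LABEL_MAP, LabelVolume3D, ScalarVolume3D,
                        read_label_volume, read_scalar_volume,
                        write_map_nifti, write_maps_png)

log = logging.getLogger("vertemap.pipeline")

STAT_COLUMNS = ["subject", "vertebra", "source", "mean", "min", "max", "sd",
                "n", "inclination_deg"]


@dataclass
class RunConfig:
    """Everything one subject run needs; mirrors the CLI flags."""

    pdff_path: str = ""
    labels_path: str = ""
    truth_path: str | None = None
    out_dir: str = "."
    subject_id: str = "subject"
    label_map: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    n_major: int = 20
    n_minor: int = 16
    n_long: int = 20
    hough_half_range_deg: float = 30.0
    hough_resolution_deg: float = 0.5
    hough_offset_bin_mm: float | None = None  # None: match the slice pitch
    hough_min_edge_points: int = 5
    roi_margin_voxels: int = 2
    correct_inclination: bool = True
    log_level: str = "INFO"

    @property
    def geometry(self) -> TemplateGeometry:
        return TemplateGeometry(self.n_major, self.n_minor, self.n_long)

    @property
    def hough_kwargs(self) -> dict:
        return {
            "half_range_deg": self.hough_half_range_deg,
            "resolution_deg": self.hough_resolution_deg,
            "offset_bin_mm": self.hough_offset_bin_mm,
            "min_edge_points": self.hough_min_edge_points,
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["label_map"] = {int(k): v
                            for k, v in raw.get("label_map",
                                                DEFAULT_LABEL_MAP).items()}
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SubjectResult:
    subject_id: str
    table: pd.DataFrame
    maps: dict[str, dict[str, StandardizedMaps]]     # label -> variant -> maps
    angles_deg: dict[str, float]
    confusion: pd.DataFrame | None = None


def _ordered_labels(labels: LabelVolume3D) -> list[int]:
    """Present labels, inferior-first (L5 before L1 under the default map)."""
    return sorted(labels.present_labels(), reverse=True)


def analyze_subject(
    scalar: ScalarVolume3D,
    labels: LabelVolume3D,
    config: RunConfig | None = None,
) -> SubjectResult:
    """Run the full per-vertebra workflow on in-memory volumes."""
    config = config or RunConfig()
    rows: list[dict] = []
    maps_out: dict[str, dict[str, StandardizedMaps]] = {}
    angles: dict[str, float] = {}

    for label in _ordered_labels(labels):
        try:
            roi = extract_vertebra_roi(scalar, labels, label,
                                       margin_voxels=config.roi_margin_voxels)
        except LabelError as exc:
            log.warning("skipping label %d: %s", label, exc)
            continue
        name = roi.label_name

        est = estimate_roi_inclination(roi, **config.hough_kwargs)
        angles[name] = est.angle_deg if est.valid else float("nan")
        if not est.valid:
            log.warning("%s: inclination estimate invalid "
                        "(%d edge points)", name, est.n_edge_points)

        vstats = volumetric_stats(roi)
        variants = {"uncorrected": build_standardized_maps(
            roi, config.geometry, correct_inclination=False)}
        if config.correct_inclination:
            variants["corrected"] = build_standardized_maps(
                roi, config.geometry, correct_inclination=True,
                hough_kwargs=config.hough_kwargs)
        maps_out[name] = variants

        rows.append({"subject": config.subject_id, "vertebra": name,
                     "source": "volumetric", "mean": vstats.mean,
                     "min": vstats.min, "max": vstats.max, "sd": vstats.sd,
                     "n": vstats.n, "inclination_deg": angles[name]})
        for variant, mp in variants.items():
            ms = map_stats(mp)
            source = ("maps_pooled" if variant == "uncorrected"
                      else "maps_pooled_corrected")
            rows.append({"subject": config.subject_id, "vertebra": name,
                         "source": source, "mean": ms.mean, "min": ms.min,
                         "max": ms.max, "sd": ms.sd, "n": ms.n,
                         "inclination_deg": mp.inclination_deg})

    table = pd.DataFrame(rows, columns=STAT_COLUMNS)
    return SubjectResult(subject_id=config.subject_id, table=table,
                         maps=maps_out, angles_deg=angles)


def _evaluate_against_truth(
    labels: LabelVolume3D, truth: LabelVolume3D, subject_id: str
) -> pd.DataFrame:
    rows = []
    voxvol = float(np.prod(labels.spacing_mm)) / 1000.0
    for label in _ordered_labels(truth):
        cm = confusion_metrics(labels.data == label, truth.data == label,
                               voxvol)
        row = {"subject": subject_id, "vertebra": truth.label_map[label]}
        row.update(asdict(cm))
        rows.append(row)
    return pd.DataFrame(rows)


def run_subject(config: RunConfig) -> SubjectResult:
    """File-based subject run: read NIfTI inputs, write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scalar = read_scalar_volume(config.pdff_path)
    labels = read_label_volume(config.labels_path, config.label_map)
    if scalar.data.shape != labels.data.shape:
        raise ValueError("PDFF and label volumes have different shapes")

    result = analyze_subject(scalar, labels, config)
    result.table.to_csv(out / "stats.csv", index=False,
                        float_format="%.6f")

    for name, variants in result.maps.items():
        mp = variants.get("corrected", variants["uncorrected"])
        for plane, (arr, _ok) in mp.planes().items():
            write_map_nifti(arr, out / f"map_{name}_{plane}.nii.gz")
        write_maps_png(mp, out / f"maps_{name}.png")

    if config.truth_path:
        truth = read_label_volume(config.truth_path, config.label_map)
        result.confusion = _evaluate_against_truth(labels, truth,
                                                   config.subject_id)
        result.confusion.to_csv(out / "segmentation_metrics.csv",
                                index=False, float_format="%.6f")

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "clipped_voxels": scalar.n_clipped,
        "inclination_deg": result.angles_deg,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return result


# ---------------------------------------------------------------------------
# Cohort level


@dataclass
class CohortSummary:
    """Group-wise tables plus agreement of maps against volumetry."""

    summary: pd.DataFrame        # group x vertebra x statistic, mean ± SD
    comparisons: pd.DataFrame    # pairwise group tests per vertebra/statistic
    agreement: "pd.Series | None"  # Bland-Altman of maps vs volumetric means


VERTEBRA_ORDER = ["L5", "L4", "L3", "L2", "L1"]
SUMMARY_STATS = ["mean", "min", "max", "sd"]


def run_cohort(
    results: list[SubjectResult],
    groups: dict[str, str],
    *,
    source: str = "maps_pooled",
    alpha: float = 0.05,
) -> CohortSummary:
    """Aggregate subject results into group-wise tables and tests.

    ``groups`` maps subject id to group name.  Per group and vertebra the
    mean ± SD of each statistic is tabulated (columns ordered L5 → L1);
    groups are compared pairwise per vertebra and statistic with the
    normality-gated two-sample test; groups with fewer than 3 subjects are
    excluded from testing with a warning.  Bland–Altman agreement pools all
    (subject, vertebra) pairs of map-derived vs volumetric mean PDFF.
    """
    if not results:
        raise ValueError("no subject results")
    big = pd.concat([r.table for r in results], ignore_index=True)
    big["group"] = big["subject"].map(groups)
    if big["group"].isna().any():
        missing = sorted(big.loc[big["group"].isna(), "subject"].unique())
        raise ValueError(f"subjects without group assignment: {missing}")
    present_vertebrae = [v for v in VERTEBRA_ORDER
                         if v in set(big["vertebra"])]
    src = big[big["source"] == source]

    rows = []
    for group, gdf in src.groupby("group", sort=True):
        for stat in SUMMARY_STATS:
            row: dict = {"group": group, "statistic": stat}
            for vert in present_vertebrae:
                vals = gdf.loc[gdf["vertebra"] == vert, stat].to_numpy()
                if vals.size:
                    row[vert] = f"{vals.mean():.1f} ± {_sd(vals):.1f}"
            rows.append(row)
    summary = pd.DataFrame(rows,
                           columns=["group", "statistic", *present_vertebrae])

    group_sizes = src.groupby("group")["subject"].nunique()
    testable = [g for g, n in group_sizes.items() if n >= 3]
    for g, n in group_sizes.items():
        if n < 3:
            log.warning("group %r has %d subject(s); comparisons skipped",
                        g, n)

    comp_rows = []
    for i, ga in enumerate(testable):
        for gb in testable[i + 1:]:
            for vert in present_vertebrae:
                for stat in SUMMARY_STATS:
                    va = src.loc[(src["group"] == ga)
                                 & (src["vertebra"] == vert), stat].to_numpy()
                    vb = src.loc[(src["group"] == gb)
                                 & (src["vertebra"] == vert), stat].to_numpy()
                    if va.size < 3 or vb.size < 3:
                        continue
                    res = compare_groups(va, vb, alpha=alpha)
                    comp_rows.append({
                        "group_a": ga, "group_b": gb, "vertebra": vert,
                        "statistic": stat, "test": res.test_name,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    })
    comparisons = pd.DataFrame(
        comp_rows, columns=["group_a", "group_b", "vertebra", "statistic",
                            "test", "p_value", "significant"])

    vol = big[big["source"] == "volumetric"]
    merged = pd.merge(
        vol[["subject", "vertebra", "mean"]],
        src[["subject", "vertebra", "mean"]],
        on=["subject", "vertebra"], suffixes=("_vol", "_map"))
    agreement = None
    if len(merged) >= 2:
        ba = bland_altman(merged["mean_vol"].to_numpy(),
                          merged["mean_map"].to_numpy())
        agreement = pd.Series(asdict(ba))
    return CohortSummary(summary=summary, comparisons=comparisons,
                         agreement=agreement)


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0
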