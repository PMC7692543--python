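"""The two-stage decision protocol for isolating coccospheres.

Order of gates (each object receives exactly one label):

1. detection / birefringence - objects with nothing above background, or a
   maximum intensity below the birefringence threshold, are
   ``nonbirefringent`` (cross-polarised optics reject isotropic material);
2. focus - Gradient RMS must exceed ``grms_min`` (strict >, default 15);
3. singlet - aspect ratio must exceed ``ar_min`` (strict >, default 0.75);
4. optional speed-bead exclusion by diameter and aspect-ratio windows;
5. region R1 - diameter in ``diam_range`` (default 3-30 um, inclusive) and
   circularity >= ``circ_min`` (default 10); failures are
   ``birefringent_other``;
6. region R2 - bright-spot count: in *field* mode <= 4 spots -> coccolith,
   5-9 -> review (exported for manual inspection), >= 10 -> coccosphere
   (the "pure" population); in *control* mode, where only cultured
   coccolithophore material is present, >= 5 -> coccosphere, < 5 ->
   coccolith.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError, InvalidParameterError
from .features import extract_feature_table
from .masking import MaskConfig, ObjectImage


class GateLabel(str, Enum):
    """Final class assigned to each object by the protocol."""

    UNFOCUSED = "unfocused"
    DOUBLET = "doublet"
    BEAD = "bead"
    NONBIREFRINGENT = "nonbirefringent"
    BIREFRINGENT_OTHER = "birefringent_other"
    COCCOLITH = "coccolith"
    REVIEW = "review"
    COCCOSPHERE = "coccosphere"


ALL_LABELS = [lbl.value for lbl in GateLabel]


@dataclass(frozen=True)
class GateConfig:
    """All thresholds of the decision protocol (defaults = field template).

    Boundary conventions follow the protocol's wording: focus and singlet
    comparisons are strict (>), circularity and spot-count gates inclusive
    (>=), and the diameter and spot-area intervals are closed.
    """

    grms_min: float = 15.0
    ar_min: float = 0.75
    biref_min_intensity: float = 15.0
    diam_range: tuple[float, float] = (3.0, 30.0)
    circ_min: float = 10.0
    spot_coccolith_max: int = 4
    spot_review_band: tuple[int, int] = (5, 9)
    spot_pure_min: int = 10
    spot_area_range: tuple[float, float] = (0.56, 555.56)
    spot_to_bg_ratio: float = 3.0
    detail_radius_um: float = 1.7
    bead_diam_window: tuple[float, float] | None = None
    bead_ar_window: tuple[float, float] | None = None
    pixel_area: float = 0.33

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("grms_min", "ar_min", "circ_min", "spot_to_bg_ratio"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if not self.pixel_area > 0:
            raise ConfigError("pixel_area must be positive")
        for name in ("diam_range", "spot_area_range", "spot_review_band"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must be ordered (low, high), got {lo} > {hi}")
        for name in ("bead_diam_window", "bead_ar_window"):
            win = getattr(self, name)
            if win is not None and win[0] > win[1]:
                raise ConfigError(f"{name} must be ordered (low, high)")
        if self.spot_review_band[1] != self.spot_pure_min - 1:
            raise ConfigError(
                "spot_review_band upper edge must equal spot_pure_min - 1 "
                f"({self.spot_review_band[1]} != {self.spot_pure_min - 1})"
            )
        if self.spot_review_band[0] != self.spot_coccolith_max + 1:
            raise ConfigError(
                "spot_review_band lower edge must equal spot_coccolith_max + 1"
            )

    def mask_config(self) -> MaskConfig:
        return MaskConfig(
            spot_to_bg_ratio=self.spot_to_bg_ratio,
            detail_radius_um=self.detail_radius_um,
            spot_area_range=self.spot_area_range,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GateConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        kwargs = {}
        for key, val in data.items():
            if isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)


@dataclass
class PopulationSummary:
    """Counts and size statistics of a gated gallery."""

    total_objects: int
    counts_per_label: dict
    coccosphere_fraction: float
    event_rate_per_s: float | None = None
    diameter_stats: dict | None = None
    diameter_histogram: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class TemplateResult:
    """Coccosphere-region bounds derived from control samples."""

    diam_range: tuple[float, float]
    circ_min: float
    contamination_fraction: float | None

    def apply_to(self, config: GateConfig) -> GateConfig:
        return replace(config, diam_range=self.diam_range, circ_min=self.circ_min)


def _require_columns(records: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise InvalidInputError(f"records missing column(s): {missing}")


def birefringence_filter(
    records: pd.DataFrame, biref_min_intensity: float = 15.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (birefringent, nonbirefringent) by maximum intensity.

    Only detected objects with ``max_intensity >= biref_min_intensity`` are
    birefringent; non-detections are non-birefringent by definition.
    """
    _require_columns(records, ("max_intensity", "detected"))
    keep = records["detected"].astype(bool) & (
        records["max_intensity"] >= biref_min_intensity
    )
    return records[keep], records[~keep]


def focus_filter(
    records: pd.DataFrame, grms_min: float = 15.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep records with Gradient RMS strictly greater than ``grms_min``."""
    _require_columns(records, ("gradient_rms",))
    keep = records["gradient_rms"] > grms_min
    return records[keep], records[~keep]


def singlet_filter(
    records: pd.DataFrame, ar_min: float = 0.75
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep records with aspect ratio strictly greater than ``ar_min``."""
    _require_columns(records, ("aspect_ratio",))
    keep = records["aspect_ratio"] > ar_min
    return records[keep], records[~keep]


def bead_exclusion(
    records: pd.DataFrame, config: GateConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove calibration speed beads by diameter x aspect-ratio windows.

    A no-op (everything retained) when either window is unset.
    """
    if config.bead_diam_window is None or config.bead_ar_window is None:
        return records, records.iloc[0:0]
    _require_columns(records, ("diameter_um", "aspect_ratio"))
    d_lo, d_hi = config.bead_diam_window
    a_lo, a_hi = config.bead_ar_window
    is_bead = (
        records["diameter_um"].between(d_lo, d_hi)
        & records["aspect_ratio"].between(a_lo, a_hi)
    )
    return records[~is_bead], records[is_bead]


def region_R1(
    records: pd.DataFrame,
    diam_range: tuple[float, float] = (3.0, 30.0),
    circ_min: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coccosphere/coccolith region: diameter in range and circularity >= min."""
    _require_columns(records, ("diameter_um", "circularity"))
    lo, hi = diam_range
    inside = records["diameter_um"].between(lo, hi) & (
        records["circularity"] >= circ_min
    )
    return records[inside], records[~inside]


def region_R2(
    records: pd.DataFrame,
    config: GateConfig | None = None,
    mode: str = "field",
) -> pd.Series:
    """Label R1 survivors by bright-spot count.

    Field mode: <= ``spot_coccolith_max`` -> coccolith, review band ->
    review, >= ``spot_pure_min`` -> coccosphere. Control mode (cultured
    material only): >= review-band low edge -> coccosphere, else coccolith.
    """
    cfg = config or GateConfig()
    if mode not in ("field", "control"):
        raise InvalidParameterError(f"mode must be 'field' or 'control', got {mode!r}")
    _require_columns(records, ("spot_count",))
    spots = records["spot_count"]
    if mode == "control":
        labels = np.where(
            spots >= cfg.spot_review_band[0],
            GateLabel.COCCOSPHERE.value,
            GateLabel.COCCOLITH.value,
        )
    else:
        labels = np.full(len(records), GateLabel.REVIEW.value, dtype=object)
        labels[spots.to_numpy() <= cfg.spot_coccolith_max] = GateLabel.COCCOLITH.value
        labels[spots.to_numpy() >= cfg.spot_pure_min] = GateLabel.COCCOSPHERE.value
    return pd.Series(labels, index=records.index, name="label")


def derive_template(
    pos_records: pd.DataFrame, neg_records: pd.DataFrame | None = None
) -> TemplateResult:
    """Derive coccosphere-region bounds from control samples.

    The region is the [min, max] diameter and minimum circularity observed
    on visually confirmed coccospheres (positive control); the
    contamination fraction is the share of negative-control particles
    (sediment with the calcite dissolved out) that fall inside it.
    """
    if pos_records is None or len(pos_records) == 0:
        raise InvalidInputError("positive control record set is empty")
    _require_columns(pos_records, ("diameter_um", "circularity"))
    diam_range = (
        float(pos_records["diameter_um"].min()),
        float(pos_records["diameter_um"].max()),
    )
    circ_min = float(pos_records["circularity"].min())
    contamination: float | None = None
    if neg_records is not None and len(neg_records) > 0:
        _require_columns(neg_records, ("diameter_um", "circularity"))
        inside, _ = region_R1(neg_records, diam_range, circ_min)
        contamination = len(inside) / len(neg_records)
    return TemplateResult(diam_range, circ_min, contamination)


def label_records(
    records: pd.DataFrame, config: GateConfig | None = None, mode: str = "field"
) -> pd.DataFrame:
    """Apply the full gate sequence to a feature table.

    Returns a copy with ``label`` and ``stage`` columns; every record gets
    exactly one label, decided by the first gate that rejects it (or by R2).
    """
    cfg = config or GateConfig()
    if mode not in ("field", "control"):
        raise InvalidParameterError(f"mode must be 'field' or 'control', got {mode!r}")
    out = records.copy()
    out["label"] = ""
    out["stage"] = ""

    detected = out["detected"].astype(bool)
    out.loc[~detected, ["label", "stage"]] = [
        GateLabel.NONBIREFRINGENT.value,
        "detection",
    ]
    remaining = out[detected]

    kept, dropped = focus_filter(remaining, cfg.grms_min)
    out.loc[dropped.index, ["label", "stage"]] = [GateLabel.UNFOCUSED.value, "focus"]

    kept, dropped = singlet_filter(kept, cfg.ar_min)
    out.loc[dropped.index, ["label", "stage"]] = [GateLabel.DOUBLET.value, "singlet"]

    kept, dropped = bead_exclusion(kept, cfg)
    out.loc[dropped.index, ["label", "stage"]] = [GateLabel.BEAD.value, "bead"]

    kept, dropped = birefringence_filter(kept, cfg.biref_min_intensity)
    out.loc[dropped.index, ["label", "stage"]] = [
        GateLabel.NONBIREFRINGENT.value,
        "birefringence",
    ]

    kept, dropped = region_R1(kept, cfg.diam_range, cfg.circ_min)
    out.loc[dropped.index, ["label", "stage"]] = [
        GateLabel.BIREFRINGENT_OTHER.value,
        "R1",
    ]

    if len(kept):
        out.loc[kept.index, "label"] = region_R2(kept, cfg, mode)
        out.loc[kept.index, "stage"] = "R2"
    return out


def event_rate(count: int, seconds: float) -> float:
    """Objects detected per second of acquisition."""
    if not seconds > 0:
        raise InvalidParameterError("seconds must be > 0")
    return count / seconds


def summarise(
    labelled: pd.DataFrame,
    acquisition_seconds: float | None = None,
    bin_width_um: float = 1.0,
) -> PopulationSummary:
    """Population summary over a labelled feature table.

    ``coccosphere_fraction`` is the pure-coccosphere count over the number
    of birefringent objects that reached the morphology gates (labels
    birefringent_other / coccolith / review / coccosphere).
    """
    counts = {lbl: 0 for lbl in ALL_LABELS}
    if len(labelled):
        observed = labelled["label"].value_counts().to_dict()
        counts.update({k: int(v) for k, v in observed.items()})
    total = int(len(labelled))
    biref_labels = (
        GateLabel.BIREFRINGENT_OTHER.value,
        GateLabel.COCCOLITH.value,
        GateLabel.REVIEW.value,
        GateLabel.COCCOSPHERE.value,
    )
    n_biref = sum(counts[lbl] for lbl in biref_labels)
    n_cocco = counts[GateLabel.COCCOSPHERE.value]
    fraction = n_cocco / n_biref if n_biref else 0.0

    stats = None
    hist = None
    if n_cocco:
        diam = labelled.loc[
            labelled["label"] == GateLabel.COCCOSPHERE.value, "diameter_um"
        ].to_numpy()
        stats = {
            "n": int(diam.size),
            "mean_um": float(diam.mean()),
            "sd_um": float(diam.std(ddof=1)) if diam.size > 1 else 0.0,
            "min_um": float(diam.min()),
            "max_um": float(diam.max()),
        }
        lo = np.floor(diam.min() / bin_width_um) * bin_width_um
        hi = np.ceil(diam.max() / bin_width_um) * bin_width_um + bin_width_um
        edges = np.arange(lo, hi + bin_width_um / 2, bin_width_um)
        binned, edges = np.histogram(diam, bins=edges)
        hist = {"bin_edges_um": edges.tolist(), "counts": binned.tolist()}

    rate = None
    if acquisition_seconds is not None:
        rate = event_rate(total, acquisition_seconds)
    return PopulationSummary(
        total_objects=total,
        counts_per_label=counts,
        coccosphere_fraction=fraction,
        event_rate_per_s=rate,
        diameter_stats=stats,
        diameter_histogram=hist,
    )


def run_pipeline(
    gallery: list[ObjectImage],
    config: GateConfig | None = None,
    mode: str = "field",
    acquisition_seconds: float | None = None,
) -> tuple[pd.DataFrame, PopulationSummary]:
    """Features + gates + summary for a gallery of object images."""
    cfg = config or GateConfig()
    table = extract_feature_table(gallery, cfg.mask_config())
    if table.empty:
        table["label"] = pd.Series(dtype=object)
        table["stage"] = pd.Series(dtype=object)
        return table, summarise(table, acquisition_seconds)
    labelled = label_records(table, cfg, mode)
    return labelled, summarise(labelled, acquisition_seconds)
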