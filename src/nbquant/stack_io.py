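"""Stack reading/writing, tabular output and pipeline orchestration.

The unit of analysis is a :class:`ChannelStack`: one fluorescence channel of
a confocal Z-stack held as a ``uint8`` voxel grid (Z, Y, X) together with its
physical voxel size in micrometres.  Two-channel acquisitions (channel 1 =
protein of interest, typically coilin; channel 2 = DAPI) are returned as a
list of two stacks.

All intensity thresholds elsewhere in the package are expressed on the 8-bit
[0, 255] scale, so 16-bit sources are linearly min-max rescaled to 8 bits on
input and the scale factors are recorded.

:func:`run_pipeline` chains the three analysis stages — nucleus cropping,
body segmentation, morphometry — and emits the per-nucleus cohort table as
CSV plus label images and a JSON run log.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import ConfigurationError, PipelineError, StackIOError

logger = logging.getLogger(__name__)

PROTEIN = "protein"
DAPI = "dapi"

#: Fixed column set of the cohort CSV, one row per nucleus.
COHORT_COLUMNS = [
    "source_id",
    "group",
    "n_bodies",
    "mean_diameter_um",
    "mean_max_intensity",
    "cytoplasmic_flag",
    "excluded",
    "exclusion_reason",
]


@dataclass
class ChannelStack:
    """A single-channel 3D voxel grid with physical voxel dimensions.

    Parameters
    ----------
    voxels
        ``uint8`` array of shape (Z, Y, X); intensities in [0, 255] a.u.
    voxel_size
        (dz, dy, dx) in micrometres per voxel.  Axial sampling is usually
        coarser than lateral (dz >= dx); anisotropy is carried through all
        downstream computations and never assumed away.
    channel_role
        Either ``"protein"`` or ``"dapi"``.
    source_id
        Opaque identifier of the originating stack (file stem by default).
    rescale
        ``None`` for native 8-bit input, otherwise the (min, max) of the
        original data that were mapped to (0, 255).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_role: str = PROTEIN
    source_id: str = ""
    rescale: Optional[tuple[float, float]] = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ConfigurationError(
                f"voxel grid must be 3D with positive extents, got shape {self.voxels.shape}"
            )
        if self.voxels.dtype != np.uint8:
            if self.voxels.min() < 0 or self.voxels.max() > 255:
                raise ConfigurationError("intensities must lie in [0, 255]")
            self.voxels = self.voxels.astype(np.uint8)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        if self.channel_role not in (PROTEIN, DAPI):
            raise ConfigurationError(f"unknown channel_role {self.channel_role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


def _rescale_to_uint8(arr: np.ndarray) -> tuple[np.ndarray, Optional[tuple[float, float]]]:
    """Linear min-max rescale to [0, 255]; identity on uint8 input."""
    if arr.dtype == np.uint8:
        return arr, None
    lo = float(arr.min())
    hi = float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8), (lo, hi)
    scaled = np.rint((arr.astype(np.float64) - lo) * (255.0 / (hi - lo)))
    return scaled.astype(np.uint8), (lo, hi)


def _voxel_size_from_ome(tif: tifffile.TiffFile) -> Optional[tuple[float, float, float]]:
    if not tif.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        pixels = image["Pixels"]
        dz = pixels.get("PhysicalSizeZ")
        dy = pixels.get("PhysicalSizeY")
        dx = pixels.get("PhysicalSizeX")
    except (KeyError, TypeError):
        return None
    if dz is None or dy is None or dx is None:
        return None
    return float(dz), float(dy), float(dx)


def read_stack(
    path,
    voxel_size_override: Optional[tuple[float, float, float]] = None,
    channel_roles: Optional[Sequence[str]] = None,
) -> list[ChannelStack]:
    """Read a single- or two-channel Z-stack from (OME-)TIFF.

    Returns one :class:`ChannelStack` per channel.  By convention channel 1
    is the protein of interest and channel 2 is DAPI; pass ``channel_roles``
    to override.  16-bit data are linearly min-max rescaled per channel to
    the 8-bit analysis scale.

    Raises
    ------
    StackIOError
        If the file cannot be read.
    ConfigurationError
        If no voxel size is available (neither metadata nor override), or
        the file has more than two channels and no explicit role mapping.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            meta_voxel = _voxel_size_from_ome(tif)
    except (FileNotFoundError, OSError, ValueError, IndexError) as exc:
        raise StackIOError(f"cannot read image stack {path}: {exc}") from exc

    # Normalise to (C, Z, Y, X)
    axes = axes.upper().replace("S", "C")
    if axes in ("YX",):
        data = data[np.newaxis, np.newaxis]
    elif axes in ("ZYX", "QYX", "IYX"):
        data = data[np.newaxis]
    elif axes == "CZYX":
        pass
    elif axes == "ZCYX":
        data = np.swapaxes(data, 0, 1)
    elif axes == "CYX":
        data = data[:, np.newaxis]
    else:
        raise ConfigurationError(f"unsupported axis layout {axes!r} in {path}")

    n_channels = data.shape[0]
    if channel_roles is None:
        if n_channels == 1:
            channel_roles = [PROTEIN]
        elif n_channels == 2:
            channel_roles = [PROTEIN, DAPI]
        else:
            raise ConfigurationError(
                f"{path} has {n_channels} channels; a channel role mapping is required"
            )
    elif len(channel_roles) != n_channels:
        raise ConfigurationError(
            f"{len(channel_roles)} channel roles given for {n_channels} channels in {path}"
        )

    voxel_size = voxel_size_override or meta_voxel
    if voxel_size is None:
        raise ConfigurationError(
            f"{path} carries no voxel-size metadata; pass voxel_size_override"
        )

    stacks = []
    for c, role in enumerate(channel_roles):
        voxels, rescale = _rescale_to_uint8(data[c])
        if rescale is not None:
            logger.info(
                "rescaled %s channel %d from [%g, %g] to 8-bit", path.name, c, *rescale
            )
        stacks.append(
            ChannelStack(
                voxels=voxels,
                voxel_size=tuple(voxel_size),
                channel_role=role,
                source_id=path.stem.replace(".ome", ""),
                rescale=rescale,
            )
        )
    return stacks


def write_channel_stacks(path, stacks: Sequence[ChannelStack]) -> None:
    """Write channels as one OME-TIFF (axes CZYX) with voxel-size metadata."""
    path = Path(path)
    data = np.stack([s.voxels for s in stacks])
    dz, dy, dx = stacks[0].voxel_size
    try:
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={
                "axes": "CZYX",
                "PhysicalSizeZ": dz,
                "PhysicalSizeZUnit": "µm",
                "PhysicalSizeY": dy,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeX": dx,
                "PhysicalSizeXUnit": "µm",
            },
        )
    except OSError as exc:
        raise StackIOError(f"cannot write {path}: {exc}") from exc


def write_label_image(path, labels: np.ndarray) -> None:
    """Write a 3D label image as 16-bit TIFF."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise StackIOError(f"too many labels for 16-bit output: {labels.max()}")
    try:
        tifffile.imwrite(Path(path), labels.astype(np.uint16))
    except OSError as exc:
        raise StackIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Cohort table CSV


def write_cohort_table(table: pd.DataFrame, path) -> None:
    """Write the per-nucleus cohort table as CSV (UTF-8, '.' decimal).

    Nuclei with zero bodies have their mean columns emitted as empty fields
    (absence, not zero).  The written file re-reads to an identical table
    via :func:`read_cohort_table`.
    """
    if len(table) == 0:
        raise ConfigurationError("refusing to write an empty cohort table")
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"cohort table lacks columns {missing}")
    out = table[COHORT_COLUMNS].copy()
    buf = io.StringIO()
    out.to_csv(buf, index=False, lineterminator="\n")
    try:
        Path(path).write_text(buf.getvalue(), encoding="utf-8")
    except OSError as exc:
        raise StackIOError(f"cannot write cohort table {path}: {exc}") from exc


def _parse_flag(tok: str):
    if tok == "":
        return pd.NA
    return tok == "True"


def read_cohort_table(path) -> pd.DataFrame:
    """Read a cohort CSV back into the canonical dtypes.

    ``cytoplasmic_flag`` is a nullable boolean: it is absent for nuclei where
    the cytoplasmic shell could not be evaluated.
    """
    try:
        df = pd.read_csv(
            Path(path),
            dtype={
                "source_id": str,
                "group": str,
                "exclusion_reason": str,
            },
            converters={"cytoplasmic_flag": _parse_flag, "excluded": lambda t: t == "True"},
        )
    except (FileNotFoundError, OSError) as exc:
        raise StackIOError(f"cannot read cohort table {path}: {exc}") from exc
    df["n_bodies"] = df["n_bodies"].astype(np.int64)
    df["mean_diameter_um"] = pd.to_numeric(df["mean_diameter_um"], errors="coerce")
    df["mean_max_intensity"] = pd.to_numeric(df["mean_max_intensity"], errors="coerce")
    df["cytoplasmic_flag"] = df["cytoplasmic_flag"].astype("boolean")
    df["excluded"] = df["excluded"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run.

    Round-trips losslessly through YAML; the seed fully determines any
    stochastic step (the imaging pipeline itself is deterministic, the seed
    is consumed by permutation tests and the simulator).
    """

    segmentation: "SegmentationParams" = None  # type: ignore[assignment]
    nucleus: "NucleusParams" = None  # type: ignore[assignment]
    exclusions: list = field(default_factory=list)
    group_map: dict = field(default_factory=dict)
    group_order: list = field(default_factory=lambda: ["young", "middle", "old"])
    voxel_size_override: Optional[tuple[float, float, float]] = None
    protein_channel: int = 0
    dapi_channel: int = 1
    auto_saturation: bool = True
    saturation_fraction: float = 0.01
    output_dir: str = "nbquant_out"
    seed: int = 0

    def __post_init__(self):
        from .body_segmenter import SegmentationParams
        from .nucleus_finder import NucleusParams

        if self.segmentation is None:
            self.segmentation = SegmentationParams()
        elif isinstance(self.segmentation, dict):
            self.segmentation = SegmentationParams(**self.segmentation)
        if self.nucleus is None:
            self.nucleus = NucleusParams()
        elif isinstance(self.nucleus, dict):
            self.nucleus = NucleusParams(**self.nucleus)
        if self.voxel_size_override is not None:
            self.voxel_size_override = tuple(float(v) for v in self.voxel_size_override)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        if d["voxel_size_override"] is not None:
            d["voxel_size_override"] = list(d["voxel_size_override"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ConfigurationError("config YAML must be a mapping")
        return cls(**d)


# ---------------------------------------------------------------------------
# Pipeline orchestration


def run_pipeline(
    config: PipelineConfig,
    stack_paths: Sequence,
    write_outputs: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run cropping, segmentation and morphometry over a set of stacks.

    Returns the cohort table (one row per nucleus, exclusions flagged but
    never dropped) and a run log with per-stage object counts.  Deterministic
    given (inputs, config, seed): two runs produce byte-identical CSVs.

    Raises :class:`PipelineError` naming the stage and source on failure.
    """
    from . import body_segmenter, morphometry, nucleus_finder, qc_filter

    out_dir = Path(config.output_dir)
    if write_outputs:
        (out_dir / "crops").mkdir(parents=True, exist_ok=True)
        (out_dir / "labels").mkdir(parents=True, exist_ok=True)

    all_metrics: list[dict] = []
    auto_flags: dict[str, str] = {}
    object_rows: list[dict] = []
    log: dict = {"stacks": [], "warnings": []}

    for path in stack_paths:
        path = Path(path)
        try:
            stacks = read_stack(path, voxel_size_override=config.voxel_size_override)
        except (StackIOError, ConfigurationError) as exc:
            raise PipelineError("read", str(path), str(exc)) from exc
        sid = stacks[0].source_id
        if len(stacks) < 2:
            raise PipelineError("read", sid, "two channels (protein, DAPI) are required")
        protein = stacks[config.protein_channel]
        dapi = stacks[config.dapi_channel]
        protein.channel_role = PROTEIN
        dapi.channel_role = DAPI
        group = config.group_map.get(sid, "unspecified")

        try:
            labels = nucleus_finder.segment_nuclei(dapi, config.nucleus)
            records = nucleus_finder.crop_nuclei((protein, dapi), labels, config.nucleus)
        except Exception as exc:  # noqa: BLE001 - re-tagged with stage context
            raise PipelineError("nucleus_finder", sid, str(exc)) from exc

        n_label = int(labels.max())
        if n_label == 0:
            msg = f"{sid}: no nuclei found"
            logger.warning(msg)
            log["warnings"].append(msg)
        if write_outputs:
            write_label_image(out_dir / "labels" / f"{sid}_nuclei.tif", labels)

        stack_log = {"source_id": sid, "n_nuclei": n_label, "nuclei": []}
        for rec in records:
            nid = f"{sid}_n{rec.nucleus_id}"
            try:
                blurred = body_segmenter.gaussian_blur_3d(
                    rec.protein_crop, config.segmentation.sigma_um
                )
                seeds = body_segmenter.detect_maxima_3d(
                    blurred,
                    config.segmentation,
                    rec.nucleus_mask,
                    voxel_size=rec.protein_crop.voxel_size,
                    reference=rec.protein_crop.voxels,
                )
                body_labels = body_segmenter.segment_bodies(
                    rec.protein_crop.voxels,
                    blurred,
                    seeds,
                    config.segmentation,
                    rec.nucleus_mask,
                    voxel_size=rec.protein_crop.voxel_size,
                )
                bodies = morphometry.measure_bodies(
                    body_labels, rec.protein_crop.voxels, rec.protein_crop.voxel_size,
                    nucleus_id=rec.nucleus_id,
                )
                cyto = qc_filter.flag_cytoplasmic(
                    rec.protein_crop.voxels, rec.nucleus_mask
                )
                metrics = morphometry.summarize_nucleus(bodies, group, cyto)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("body_segmenter", nid, str(exc)) from exc

            if rec.border_touching and config.nucleus.exclude_border:
                auto_flags[nid] = qc_filter.REASON_BORDER
            elif config.auto_saturation:
                sat = float(
                    np.mean(rec.protein_crop.voxels[rec.nucleus_mask] == 255)
                )
                if sat > config.saturation_fraction:
                    auto_flags[nid] = qc_filter.REASON_SATURATION

            all_metrics.append(
                {
                    "source_id": nid,
                    "group": group,
                    "n_bodies": metrics.n_bodies,
                    "mean_diameter_um": metrics.mean_diameter_um,
                    "mean_max_intensity": metrics.mean_max_gray,
                    "cytoplasmic_flag": cyto,
                }
            )
            for b in bodies:
                object_rows.append(
                    {
                        "source_id": nid,
                        "body_id": b.body_id,
                        "voxel_count": b.voxel_count,
                        "bbox_x_um": b.bbox_extent[0],
                        "bbox_y_um": b.bbox_extent[1],
                        "bbox_z_um": b.bbox_extent[2],
                        "diameter_um": b.diameter_um,
                        "max_gray": b.max_gray,
                    }
                )
            stack_log["nuclei"].append(
                {"nucleus_id": nid, "n_bodies": metrics.n_bodies, "n_seeds": len(seeds)}
            )
            if write_outputs:
                write_channel_stacks(
                    out_dir / "crops" / f"{nid}.ome.tif", (rec.protein_crop, rec.dapi_crop)
                )
                write_label_image(out_dir / "labels" / f"{nid}_bodies.tif", body_labels)
        log["stacks"].append(stack_log)

    cohort, summary = qc_filter.apply_exclusions(
        all_metrics, config.exclusions, auto_flags
    )
    log["exclusion_summary"] = summary
    log["n_nuclei_total"] = len(cohort)
    log["n_bodies_total"] = int(cohort.loc[~cohort["excluded"], "n_bodies"].sum()) if len(cohort) else 0

    if write_outputs:
        if len(cohort):
            write_cohort_table(cohort, out_dir / "cohort.csv")
        pd.DataFrame(
            object_rows,
            columns=[
                "source_id", "body_id", "voxel_count",
                "bbox_x_um", "bbox_y_um", "bbox_z_um", "diameter_um", "max_gray",
            ],
        ).to_csv(out_dir / "objects.csv", index=False, lineterminator="\n")
        (out_dir / "run_log.json").write_text(
            json.dumps(log, indent=2, sort_keys=True), encoding="utf-8"
        )
    return cohort, log
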