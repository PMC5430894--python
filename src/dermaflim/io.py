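"""Dataset container I/O, run configuration, and the end-to-end pipeline.

One phantom dataset is a directory holding:

* ``cube.npz`` — the TCSPC cube (counts, irf, bin_width, metadata, format
  version),
* ``channels.tif`` — SHG and TPEAF as a two-page 32-bit TIFF,
* ``truth_labels.tif`` — ground-truth region labels (when simulated),
* ``truth_table.csv`` — region decay truths,
* ``config.yaml`` — configuration echo.

``run_all`` executes simulate → fit → SAAID → segment → report
deterministically for a fixed seed and writes per-stage artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import decayfit, maps, phantom, segment, stats

__all__ = [
    "DATASET_VERSION",
    "DatasetError",
    "RunConfig",
    "write_dataset",
    "read_dataset",
    "write_fitmaps",
    "write_labelmap",
    "write_report",
    "run_all",
]

logger = logging.getLogger(__name__)

DATASET_VERSION = 1


class DatasetError(ValueError):
    """Raised when a dataset container is missing members or malformed."""


# ---------------------------------------------------------------------------
# containers


def write_dataset(
    outdir: str | Path,
    cube: phantom.TCSPCCube,
    channels: phantom.ChannelMaps,
    labels: np.ndarray | None = None,
    truths: dict[str, phantom.RegionTruth] | None = None,
    config: "RunConfig | None" = None,
) -> Path:
    """Write one dataset directory; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cube.validate()
    channels.validate()
    np.savez(
        outdir / "cube.npz",
        counts=cube.counts,
        irf=cube.irf,
        bin_width=np.float64(cube.bin_width),
        metadata=json.dumps(cube.metadata, sort_keys=True),
        version=np.int64(DATASET_VERSION),
    )
    tifffile.imwrite(
        outdir / "channels.tif",
        np.stack([channels.shg, channels.tpeaf]).astype(np.float32),
        metadata={"pages": ["shg", "tpeaf"]},
    )
    if labels is not None:
        tifffile.imwrite(outdir / "truth_labels.tif", labels.astype(np.int32))
    if truths is not None:
        pd.DataFrame([dataclasses.asdict(t) for t in truths.values()]).to_csv(
            outdir / "truth_table.csv", index=False
        )
    if config is not None:
        (outdir / "config.yaml").write_text(config.to_yaml())
    return outdir


def read_dataset(path: str | Path) -> tuple[phantom.TCSPCCube, phantom.ChannelMaps]:
    """Read a dataset directory back; lossless for counts/IRF/metadata."""
    path = Path(path)
    cube_path = path / "cube.npz"
    if not cube_path.exists():
        raise DatasetError(f"missing dataset member 'cube.npz' in {path}")
    with np.load(cube_path, allow_pickle=False) as npz:
        for member in ("counts", "irf", "bin_width", "metadata", "version"):
            if member not in npz:
                raise DatasetError(f"cube.npz is missing array '{member}'")
        version = int(npz["version"])
        if version != DATASET_VERSION:
            raise DatasetError(f"unknown dataset version {version}")
        cube = phantom.TCSPCCube(
            counts=npz["counts"],
            bin_width=float(npz["bin_width"]),
            irf=npz["irf"],
            metadata=json.loads(str(npz["metadata"])),
        )
    cube.validate()
    chan_path = path / "channels.tif"
    if not chan_path.exists():
        raise DatasetError(f"missing dataset member 'channels.tif' in {path}")
    pages = tifffile.imread(chan_path)
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise DatasetError("channels.tif must hold exactly 2 pages (shg, tpeaf)")
    if pages.shape[1:] != cube.counts.shape[:2]:
        raise DatasetError("channel shape does not match the cube's spatial axes")
    channels = phantom.ChannelMaps(shg=pages[0].astype(float), tpeaf=pages[1].astype(float))
    channels.validate()
    return cube, channels


def write_fitmaps(outdir: str | Path, fitmaps: decayfit.FitMaps) -> Path:
    """FitMaps as a multi-page 32-bit TIFF plus a CSV of valid-pixel fits."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    planes = ["tau1", "tau2", "a1", "a2", "a1_pct", "amp_ratio", "tau_m", "chi2"]
    stack = np.stack([getattr(fitmaps, p) for p in planes]).astype(np.float32)
    tifffile.imwrite(outdir / "fitmaps.tif", stack, metadata={"pages": planes})
    tifffile.imwrite(outdir / "valid.tif", fitmaps.valid.astype(np.uint8))
    rows, cols = np.nonzero(fitmaps.valid)
    df = pd.DataFrame({"row": rows, "col": cols})
    for p in planes:
        df[p] = getattr(fitmaps, p)[rows, cols]
    df.to_csv(outdir / "fits.csv", index=False)
    return outdir


def read_fitmaps(outdir: str | Path) -> decayfit.FitMaps:
    outdir = Path(outdir)
    stack = tifffile.imread(outdir / "fitmaps.tif").astype(float)
    valid = tifffile.imread(outdir / "valid.tif").astype(bool)
    planes = ["tau1", "tau2", "a1", "a2", "a1_pct", "amp_ratio", "tau_m", "chi2"]
    kwargs = {p: stack[i] for i, p in enumerate(planes)}
    return decayfit.FitMaps(valid=valid, status=None, **kwargs)


def write_labelmap(path: str | Path, labelmap: segment.LabelMap) -> Path:
    """LabelMap as 8-bit TIFF with a JSON sidecar (config + components)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labelmap.labels.astype(np.uint8))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"provenance": labelmap.provenance, "capillary_report": labelmap.capillary_report},
            indent=2,
        )
    )
    return path


def write_report(outdir: str | Path, summary: stats.RegionSummary) -> Path:
    """Region summary as CSV plus JSON histograms."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.table.to_csv(outdir / "region_summary.csv")
    hists = {
        region: {
            p: {"edges": list(map(float, e)), "freq": list(map(float, f))}
            for p, (e, f) in params.items()
        }
        for region, params in summary.histograms.items()
    }
    (outdir / "histograms.json").write_text(
        json.dumps({"metadata": summary.metadata, "histograms": hists})
    )
    return outdir


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Nested configuration of one end-to-end run; YAML round-trippable."""

    phantom: phantom.PhantomConfig = field(default_factory=phantom.PhantomConfig)
    fit: decayfit.FitConfig = field(default_factory=decayfit.FitConfig)
    segment: segment.SegmentConfig = field(default_factory=segment.SegmentConfig)
    seed: int = 0
    outdir: str = "dermaflim_run"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML-friendly: tuples -> lists handled by asdict+yaml; dict keys fine.
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(dc_type, sub: dict):
            fields = {f.name: f for f in dataclasses.fields(dc_type)}
            kwargs = {}
            for k, v in sub.items():
                if k not in fields:
                    raise ValueError(f"unknown config key '{k}' for {dc_type.__name__}")
                if isinstance(v, list):
                    v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                kwargs[k] = v
            return dc_type(**kwargs)

        return cls(
            phantom=build(phantom.PhantomConfig, d.get("phantom", {})),
            fit=build(decayfit.FitConfig, d.get("fit", {})),
            segment=build(segment.SegmentConfig, d.get("segment", {})),
            seed=d.get("seed", 0),
            outdir=d.get("outdir", "dermaflim_run"),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_all(config: RunConfig) -> Path:
    """Execute simulate → fit → SAAID → segment → report; return outdir.

    Deterministic for a fixed config (including seed); every output
    directory carries the config echo and its hash.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pcfg = dataclasses.replace(config.phantom, rng_seed=config.seed)

    cube, channels, truth_maps, truth_labels = _stage("simulate")(phantom.simulate_dataset)(pcfg)
    write_dataset(
        outdir / "dataset", cube, channels, labels=truth_labels,
        truths=phantom.default_truths(pcfg.plasma_variant), config=config,
    )

    fitmaps = _stage("fit")(decayfit.fit_image)(cube, config.fit)
    write_fitmaps(outdir / "fitmaps", fitmaps)

    normalized = _stage("saaid")(maps.normalize_channels)(channels)
    saaid_map = maps.compute_saaid(normalized)
    tifffile.imwrite(outdir / "saaid.tif", saaid_map.saaid.astype(np.float32))

    labelmap = _stage("segment")(segment.segment_image)(channels, fitmaps, saaid_map, config.segment)
    write_labelmap(outdir / "labels.tif", labelmap)

    summary = _stage("report")(stats.region_summary)(fitmaps, labelmap)
    write_report(outdir / "report", summary)

    (outdir / "run.json").write_text(
        json.dumps(
            {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_valid_pixels": int(fitmaps.valid.sum()),
                "n_capillary_components": len(labelmap.capillary_report),
            },
            indent=2,
        )
    )
    (outdir / "config.yaml").write_text(config.to_yaml())
    return outdir
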