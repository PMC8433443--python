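"""File exchange: TSV decay/spectral tables, TIFF stacks, JSON sidecars.

One dialect per job: JSON for all structured results and metadata sidecars,
tab-separated text with a header for all series, TIFF for all images.  The
time-axis convention in files is bin *left edges* in ps, starting at 0 at the
acquisition-window start; sidecars record bin width, seeds, and truth
parameters so every artifact can be regenerated from its sidecar.

FLIM stacks are written one TIFF page per time bin (2-D images + time);
plain volumes one page per z-plane.  A sidecar ``<file>.json`` disambiguates
the two; when it is missing a volume is assumed and a warning logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import DecayHistogram, IRFKernel
from .segmentation import LabelVolume
from .spectra import SpectralSeries
from .synthetic_data import FlimDataset, make_irf

logger = logging.getLogger("fgflim")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=2,
                                              default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def _read_sidecar(path: Path) -> dict | None:
    sp = _sidecar_path(path)
    if not sp.exists():
        return None
    return json.loads(sp.read_text())


# ---------------------------------------------------------------------------
# decay tables
# ---------------------------------------------------------------------------

def write_decay_table(hist: DecayHistogram, path: str | Path) -> None:
    """Write a decay histogram as TSV (time_ps = bin left edges, counts)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time_ps\tcounts\n")
        for t, c in zip(hist.time_edges, hist.counts):
            fh.write(f"{t:.10g}\t{int(c)}\n")
    _write_sidecar(path, {"kind": "decay", "bin_width_ps": hist.bin_width,
                          "t0_ps": hist.t0,
                          "time_axis": "bin left edges, ps, 0 at window start",
                          "metadata": hist.metadata})


def read_decay_table(path: str | Path) -> DecayHistogram:
    """Read a TSV decay table; errors name the offending line.

    Counts written in scientific notation are accepted when integral-valued.
    The sidecar, when present, restores bin width and metadata; otherwise the
    bin width is inferred from the (required uniform, sorted) time column.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[:2] != ["time_ps", "counts"]:
        raise ValueError(f"{path}, line 1: expected header "
                         f"'time_ps\\tcounts', got {lines[0]!r}")
    times, counts = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}, line {lineno}: expected 2 columns")
        try:
            t = float(fields[0])
            c = float(fields[1])
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from None
        if c < 0:
            raise ValueError(f"{path}, line {lineno}: negative counts {c}")
        if abs(c - round(c)) > 1e-6 * max(1.0, abs(c)):
            raise ValueError(f"{path}, line {lineno}: counts {c} are not "
                             "integral")
        if times and t <= times[-1]:
            raise ValueError(f"{path}, line {lineno}: time axis not "
                             "strictly increasing")
        times.append(t)
        counts.append(int(round(c)))
    if len(times) < 2:
        raise ValueError(f"{path}: need at least 2 bins")
    diffs = np.diff(times)
    if not np.allclose(diffs, diffs[0], rtol=1e-3):
        raise ValueError(f"{path}: time bins are not uniform")

    sidecar = _read_sidecar(path)
    if sidecar is not None:
        bin_width = float(sidecar.get("bin_width_ps", diffs[0]))
        t0 = float(sidecar.get("t0_ps", times[0]))
        meta = sidecar.get("metadata", {})
    else:
        logger.warning("%s: no sidecar; inferring bin width from time column",
                       path)
        bin_width, t0, meta = float(diffs[0]), float(times[0]), {}
    return DecayHistogram(np.asarray(counts, dtype=np.int64), bin_width, t0,
                          meta)


# ---------------------------------------------------------------------------
# spectral tables
# ---------------------------------------------------------------------------

def write_spectral_table(s: SpectralSeries, path: str | Path) -> None:
    """TSV with columns wavelength_nm, intensity[, power][, background]."""
    path = Path(path)
    cols = {"wavelength_nm": s.wavelengths, "intensity": s.intensity}
    if s.power is not None:
        cols["power"] = s.power
    if s.background is not None:
        cols["background"] = s.background
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    _write_sidecar(path, {"kind": "spectral", "metadata": s.metadata})


def read_spectral_table(path: str | Path) -> SpectralSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"wavelength_nm", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    sidecar = _read_sidecar(path) or {}
    return SpectralSeries(
        df["wavelength_nm"].to_numpy(float),
        df["intensity"].to_numpy(float),
        power=df["power"].to_numpy(float) if "power" in df else None,
        background=(df["background"].to_numpy(float)
                    if "background" in df else None),
        metadata=sidecar.get("metadata", {}))


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_flim_stack(ds: FlimDataset, path: str | Path) -> None:
    """Write a 2-D FLIM dataset as a multi-page TIFF, one page per time bin.

    Counts are stored as uint16 (lossless for realistic per-bin counts); the
    sidecar records the page order, bin width, wavelength and the Gaussian
    IRF parameters needed to rebuild the kernel on read.
    """
    path = Path(path)
    data = ds.data
    if data.ndim == 4:
        if data.shape[0] != 1:
            raise ValueError("TIFF exchange supports single-plane FLIM "
                             "stacks; got a multi-z dataset")
        data = data[0]
    if data.ndim != 3:
        raise ValueError("FLIM data must be (y, x, t) or (1, y, x, t)")
    if data.max() >= 2 ** 16:
        raise ValueError("per-bin counts exceed uint16 range")
    pages = np.moveaxis(data.astype(np.uint16), -1, 0)     # (t, y, x)
    tifffile.imwrite(path, pages, photometric="minisblack")
    _write_sidecar(path, {
        "kind": "flim", "page_axis": "time", "n_pages": pages.shape[0],
        "bin_width_ps": ds.bin_width, "wavelength_nm": ds.wavelength,
        "irf": {"fwhm_ps": ds.irf.fwhm, "center_ps": ds.irf.center,
                "bin_width_ps": ds.irf.bin_width, "n_bins": ds.irf.n_bins},
        "metadata": ds.metadata})


def write_volume(volume: np.ndarray, path: str | Path,
                 metadata: dict | None = None) -> None:
    """Write a 3-D volume (or 2-D parameter map) as TIFF, pages = z."""
    path = Path(path)
    vol = np.asarray(volume)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.dtype.kind == "f":
        vol = vol.astype(np.float32)
    tifffile.imwrite(path, vol, photometric="minisblack")
    _write_sidecar(path, {"kind": "volume", "page_axis": "z",
                          "n_pages": vol.shape[0], "dtype": str(vol.dtype),
                          "metadata": metadata or {}})


def read_stack(path: str | Path) -> FlimDataset | np.ndarray:
    """Read a TIFF stack back as a FlimDataset or a plain volume.

    The sidecar decides which; a page count that contradicts the sidecar is
    an error, and a missing sidecar falls back to a plain volume with a
    logged warning.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = _read_sidecar(path)
    if sidecar is None:
        logger.warning("%s: no sidecar; returning a plain volume", path)
        return pages
    if sidecar.get("n_pages") != pages.shape[0]:
        raise ValueError(f"{path}: sidecar says {sidecar.get('n_pages')} "
                         f"pages but the file has {pages.shape[0]}")
    if sidecar.get("kind") != "flim":
        return pages
    irf_spec = sidecar["irf"]
    irf = make_irf(irf_spec["fwhm_ps"], irf_spec["bin_width_ps"],
                   irf_spec["n_bins"], irf_spec["center_ps"])
    data = np.moveaxis(pages, 0, -1)                       # (y, x, t)
    return FlimDataset(data.astype(np.int64), sidecar["bin_width_ps"], irf,
                       wavelength=sidecar.get("wavelength_nm"),
                       metadata=sidecar.get("metadata", {}))


def write_label_volume(lv: LabelVolume, path: str | Path) -> None:
    """16-bit label TIFF plus the per-object table as CSV alongside."""
    path = Path(path)
    if lv.labels.max() >= 2 ** 16:
        raise ValueError("label volume exceeds 16-bit range")
    tifffile.imwrite(path, lv.labels.astype(np.uint16),
                     photometric="minisblack")
    lv.table.to_csv(path.with_suffix(".csv"), index=False)
    _write_sidecar(path, {"kind": "labels", "page_axis": "z",
                          "n_pages": int(lv.labels.shape[0]),
                          "n_objects": lv.n_objects,
                          "metadata": lv.metadata})


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None, defaults: dict) -> dict:
    """Merge a JSON config over defaults, rejecting unknown keys."""
    resolved = dict(defaults)
    if path is not None:
        user = json.loads(Path(path).read_text())
        unknown = set(user) - set(defaults)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        resolved.update(user)
    return resolved


def write_resolved_config(config: dict, out_path: str | Path) -> None:
    """Record the fully resolved configuration beside an output artifact."""
    out_path = Path(out_path)
    target = out_path.with_name(out_path.name + ".config.json")
    target.write_text(json.dumps(config, indent=2, default=_jsonable) + "\n")
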