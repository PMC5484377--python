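"""Readers, writers, run configuration and manifests.

Formats: 4-D dynamic series and maps are NIfTI-1 (via nibabel); ROI
curves are two-column CSV (time_s, value or conc_mM); fit results and
manifests are JSON. Config files are YAML with unit-suffixed keys
(tr_s, dt_s, ktrans_per_min, ...) so seconds and minutes cannot be
silently confused.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .kinetics import ConcCurve, DynSeries

__all__ = [
    "SequenceParams",
    "read_dynamic",
    "write_nifti",
    "read_curve_csv",
    "write_curve_csv",
    "write_results",
    "load_config",
]

log = logging.getLogger("dcehybrid")


@dataclass
class SequenceParams:
    """Dynamic-acquisition parameters (config-supplied; units in names)."""

    tr_s: float = 0.005
    flip_deg: float = 20.0
    dt_s: float = 1.03
    n_baseline: int = 33
    relaxivity_per_mM_s: float = 4.39
    r10_per_s: float = 1.0 / 0.6

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def read_dynamic(path, params: SequenceParams) -> tuple[np.ndarray, np.ndarray, DynSeries]:
    """Load a 4-D NIfTI dynamic series.

    Returns (data, affine, template_series) where the template series
    carries the time axis built from the configured dt and n_baseline.
    A header TR that disagrees with the configured dt is logged as a
    warning; the config wins.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise InvalidInputError(f"expected a 4-D dynamic series, got {data.ndim}-D")
    zooms = img.header.get_zooms()
    if len(zooms) >= 4 and zooms[3] > 0 and not np.isclose(zooms[3], params.dt_s, rtol=1e-3):
        log.warning(
            "header frame time %.4f s differs from configured dt %.4f s; using config",
            zooms[3], params.dt_s,
        )
    n_t = data.shape[-1]
    t = np.arange(n_t) * params.dt_s
    template = DynSeries(t=t, si=np.zeros(n_t), n_baseline=min(params.n_baseline, n_t))
    return data, img.affine, template


def write_nifti(data: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write an array as NIfTI-1 (labels as uint8, maps as float32)."""
    path = Path(path)
    arr = data if data.dtype == np.uint8 else data.astype(np.float32)
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    return path


def read_curve_csv(path, n_baseline: int = 0, kind: str = "conc") -> ConcCurve | DynSeries:
    """Read a two-column curve CSV: time_s plus conc_mM (or value for SI)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise InvalidInputError("curve CSV must have a time_s column")
    val_col = next((c for c in ("conc_mM", "value", "si") if c in df.columns), None)
    if val_col is None:
        raise InvalidInputError("curve CSV must have a conc_mM or value column")
    t = df["time_s"].to_numpy(float)
    v = df[val_col].to_numpy(float)
    if kind == "conc":
        return ConcCurve(t=t, c=v, n_baseline=n_baseline)
    return DynSeries(t=t, si=v, n_baseline=n_baseline)


def write_curve_csv(curve, path) -> Path:
    path = Path(path)
    if isinstance(curve, ConcCurve):
        pd.DataFrame({"time_s": curve.t, "conc_mM": curve.c}).to_csv(path, index=False)
    else:
        pd.DataFrame({"time_s": curve.t, "value": curve.si}).to_csv(path, index=False)
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_results(result: dict, outdir, config: dict | None = None, seed: int | None = None) -> Path:
    """Write a result dict plus a manifest recording config hash and versions.

    Re-running with the same config and seed reproduces the manifest
    hash, making every output traceable to its inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(result, indent=2, sort_keys=True, default=_json_default)
    (outdir / "result.json").write_text(payload)
    cfg_text = json.dumps(config or {}, sort_keys=True, default=_json_default)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "result_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "versions": {"dcehybrid": _version(), "numpy": np.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir / "manifest.json"


def _version() -> str:
    from . import __version__

    return __version__


def load_config(path) -> dict:
    """Load a YAML run-config file as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidInputError("config file must contain a mapping")
    return cfg
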