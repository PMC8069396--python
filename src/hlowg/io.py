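"""Data readers, fixture generation and report serialization.

Data are plain positive reals: either a bare text file (one value per line,
``#`` comments and blank lines skipped) or a CSV with a header, from which a
named column is taken.  Fixtures are inverse-transform samples written next
to a JSON manifest recording model, parameters, size and seed, so a fixture
file is fully self-describing and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .baselines import make_baseline
from .family import HlowParams, rvs

__all__ = ["read_series", "generate_fixture", "write_report", "read_report",
           "TABLE_FITS"]

# Published point estimates for the two applications (aluminum-coupon fatigue
# lifetimes, n=101, Frechet baseline; glass-fibre strengths, n=63, exponential
# baseline).  Used to emulate those datasets by simulation when the original
# files are not supplied.
TABLE_FITS = {
    "frechet": {
        "mle": (0.0804, 3.1059, 65.4987, 1.4272),
        "lse": (0.4772, 17.3435, 27.8989, 0.2557),
        "wlse": (0.5212, 16.0827, 26.8382, 0.2491),
        "cvme": (0.4723, 17.5159, 28.1555, 0.2572),
        "bayes_sel": (0.4696, 17.1055, 27.7908, 0.2562),
        "n": 101,
    },
    "exponential": {
        "mle": (0.4016, 3.3597, 0.5530),
        "lse": (0.0028, 0.7843, 4.8391),
        "wlse": (0.1689, 3.7036, 0.6280),
        "cvme": (0.0021, 0.9555, 4.1670),
        "bayes_sel": (0.0019, 0.9711, 4.1595),
        "n": 63,
    },
}


def read_series(path, column: Optional[str] = None) -> np.ndarray:
    """Read a positive real-valued series from plain text or CSV.

    CSV dialect is assumed when a column name is given or the first
    non-comment line does not parse as a number.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no data")

    def _is_number(s: str) -> bool:
        try:
            float(s)
            return True
        except ValueError:
            return False

    if column is not None or not _is_number(lines[0].split(",")[0]):
        df = pd.read_csv(path, comment="#")
        if column is None:
            if df.shape[1] != 1:
                raise ValueError(
                    f"{path}: multiple columns, specify one of {list(df.columns)}"
                )
            column = df.columns[0]
        if column not in df.columns:
            raise ValueError(f"{path}: no column named {column!r}")
        values = df[column].to_numpy(dtype=float)
        rows = np.arange(2, len(values) + 2)  # header is row 1
    else:
        values, rows = [], []
        for idx, ln in enumerate(text.splitlines(), start=1):
            s = ln.strip()
            if not s or s.startswith("#"):
                continue
            values.append(float(s.split(",")[0]))
            rows.append(idx)
        values = np.asarray(values)
        rows = np.asarray(rows)
    bad = ~np.isfinite(values) | (values <= 0)
    if np.any(bad):
        raise ValueError(
            f"{path}: non-positive or non-finite value at row {int(rows[np.argmax(bad)])}"
        )
    return np.asarray(values, dtype=float)


def generate_fixture(model: str, params: Sequence[float], n: int, seed: int,
                     path) -> dict:
    """Write an inverse-transform sample and its JSON manifest.

    Returns the manifest dict.  The manifest is written to ``<path>.manifest.json``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lam, beta, *phi = [float(v) for v in params]
    p = HlowParams(lam, beta, make_baseline(model, phi))
    x = rvs(p, int(n), int(seed))
    path = Path(path)
    path.write_text("".join(f"{v:.12g}\n" for v in x))
    manifest = {
        "model": model,
        "params": [lam, beta, *phi],
        "n": int(n),
        "seed": int(seed),
        "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
    }
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=_json_default))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
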