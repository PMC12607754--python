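"""Machine-readable run reports bundling analysis artifacts.

A report is one JSON document embedding every result (GSI, frequency
summaries, ephys summaries, expression matrices) together with the settings
and seeds that produced them, so a run is reproducible from its report
alone.  Serialization is deterministic (sorted keys, no timestamps):
re-running with the same seed reproduces byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .errors import ValidationError

__all__ = ["build_report", "report_to_json", "plot_correlation_heatmap",
           "plot_periodogram"]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else repr(v)
    if isinstance(obj, float) and not np.isfinite(obj):
        return repr(obj)
    if hasattr(obj, "to_dict"):  # pandas
        return _jsonable(obj.to_dict())
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _window_of(artifact: Any) -> tuple[str, tuple[float, float]] | None:
    if isinstance(artifact, dict) and {"window", "start_s", "end_s"} <= artifact.keys():
        return str(artifact["window"]), (float(artifact["start_s"]),
                                         float(artifact["end_s"]))
    return None


def build_report(artifacts: dict[str, Any], seed: int | None = None) -> dict:
    """Assemble one JSON-ready report from named analysis artifacts.

    Raises when no artifacts are given, or when two artifacts define the
    same named window with different time ranges (conflicting protocols).
    """
    if not artifacts:
        raise ValidationError("build_report needs at least one artifact")
    seen: dict[str, tuple[float, float]] = {}
    for name, art in artifacts.items():
        w = _window_of(art)
        if w is not None:
            wname, rng = w
            if wname in seen and seen[wname] != rng:
                raise ValidationError(
                    f"conflicting definitions of window {wname!r}: "
                    f"{seen[wname]} vs {rng} (artifact {name!r})"
                )
            seen.setdefault(wname, rng)
    return {
        "oscsync_version": __version__,
        "seed": seed,
        "artifacts": {name: _jsonable(art) for name, art in artifacts.items()},
    }


def report_to_json(report: dict, path=None) -> str:
    text = json.dumps(report, indent=1, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def plot_correlation_heatmap(C: np.ndarray, path, labels=None, title: str = "") -> None:
    """Save a correlation-matrix heatmap (the standard GSI companion figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(np.asarray(C), vmin=-1, vmax=1, cmap="RdBu_r")
    if labels is not None:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(labels)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_periodogram(pg, path, title: str = "") -> None:
    """Save a power-spectral-density plot with the dominant frequency marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(pg.freqs_hz, pg.psd, lw=0.8)
    ax.axvline(pg.dominant_freq_hz, color="r", ls="--", lw=0.8,
               label=f"dominant {pg.dominant_freq_hz:.3g} Hz")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (a.u.$^2$)")
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
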