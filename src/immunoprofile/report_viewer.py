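"""Per-protein feature-track reports with immunogen windows highlighted.

The report object carries every per-residue track the analysis computes
(secondary structure, RSA, burial, contacts, disorder, TM/disulfide/PTM
flags), the immunogen windows of interest, and one aggregated profile per
window.  It serialises losslessly to JSON and renders as a static
multi-panel figure with the windows shaded — a headless-friendly analog of
an interactive feature viewer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .immunogen_profile import ImmunogenProfile, ImmunogenWindow, build_profile  # noqa: E402

TRACK_NAMES = ("ss3", "rsa", "buried", "contacts", "disorder",
               "is_tm", "in_disulfide", "is_ptm")
_SS_LEVEL = {"coil": 0, "helix": 1, "sheet": 2}


@dataclass
class TrackReport:
    protein_id: str
    tracks: dict[str, list]
    windows: list[tuple[str, int, int]]
    summaries: list[ImmunogenProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {name: len(v) for name, v in self.tracks.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"{self.protein_id}: unequal track lengths {lengths}")
        n = next(iter(lengths.values()), 0)
        for name, start, end in self.windows:
            if not (1 <= start <= end <= n):
                raise ValueError(
                    f"{self.protein_id}: window {name} {start}..{end} outside 1..{n}")

    @property
    def length(self) -> int:
        return len(next(iter(self.tracks.values())))

    def to_json(self) -> str:
        payload = {
            "protein_id": self.protein_id,
            "tracks": {k: list(v) for k, v in self.tracks.items()},
            "windows": [list(w) for w in self.windows],
            "summaries": [
                {**asdict(p), "window": asdict(p.window)} for p in self.summaries
            ],
        }
        return json.dumps(payload, indent=2, default=_jsonable)

    @classmethod
    def from_json(cls, text: str) -> "TrackReport":
        payload = json.loads(text)
        summaries = []
        for s in payload["summaries"]:
            w = s.pop("window")
            summaries.append(ImmunogenProfile(window=ImmunogenWindow(**w), **s))
        return cls(
            protein_id=payload["protein_id"],
            tracks=payload["tracks"],
            windows=[tuple(w) for w in payload["windows"]],
            summaries=summaries,
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def profile_tracks(features: pd.DataFrame, windows, annotations) -> TrackReport:
    """Build a TrackReport from a per-residue feature table.

    `features` is a build_feature_table frame for one protein; `windows` is
    a list of (name, start, end) in 1-based inclusive coordinates.
    """
    pids = features["protein_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"feature table must cover one protein, got {pids}")
    tracks = {name: features[name].tolist() for name in TRACK_NAMES}
    report = TrackReport(str(pids[0]), tracks, [tuple(w) for w in windows])
    ss3 = features["ss3"].tolist()
    buried = features["buried"].to_numpy()
    contacts = features["contacts"].to_numpy()
    disorder = features["disorder"].to_numpy()
    for name, start, end in report.windows:
        window = ImmunogenWindow(report.protein_id, start, end,
                                 "".join(features["aa"].tolist()[start - 1:end]))
        report.summaries.append(
            build_profile(window, ss3, buried, contacts, disorder, annotations))
    return report


def window_summary_text(report: TrackReport) -> str:
    """Plain-text per-window summaries (all profile fields)."""
    lines = [f"protein {report.protein_id} ({report.length} residues)"]
    for (name, start, end), p in zip(report.windows, report.summaries):
        lines.append(f"window {name} {start}..{end} ({p.length} residues)")
        lines.append(f"  position: {p.position_class}  disorder: {p.disorder_class}"
                     f"  majority SS: {p.majority_ss}")
        lines.append(f"  SS segments: {p.n_ss_segments}  buried residues: "
                     f"{p.n_buried}  mean contacts: {p.mean_contacts:.2f}")
        lines.append(f"  TM: {p.tm_class}  disulfide: {p.has_disulfide}"
                     f"  PTM: {p.has_ptm}")
    return "\n".join(lines)


def render_report(report: TrackReport, path: str | Path, dpi: int = 120) -> None:
    """One panel per track, immunogen windows shaded in every panel."""
    n_tracks = len(report.tracks)
    x = np.arange(1, report.length + 1)
    fig, axes = plt.subplots(n_tracks, 1, figsize=(10, 1.3 * n_tracks),
                             sharex=True, constrained_layout=True)
    for ax, (name, values) in zip(np.atleast_1d(axes), report.tracks.items()):
        if name == "ss3":
            y = [_SS_LEVEL[v] for v in values]
            ax.step(x, y, where="mid", lw=0.8)
            ax.set_yticks([0, 1, 2], ["coil", "helix", "sheet"])
        else:
            y = np.asarray(
                [np.nan if v is None else float(v) for v in values], dtype=float)
            ax.step(x, y, where="mid", lw=0.8)
        ax.set_ylabel(name, rotation=0, ha="right", va="center", fontsize=8)
        for _, start, end in report.windows:
            ax.axvspan(start - 0.5, end + 0.5, color="orange", alpha=0.25, lw=0)
    np.atleast_1d(axes)[-1].set_xlabel("residue")
    fig.suptitle(report.protein_id)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
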