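"""Plain-text readers/writers for datasets and analysis products."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .correct import HistogramSummary
from .dwells import DwellRecord
from .idealize import IdealizedTrajectory, STATE_LABELS
from .simulate import IntensityTrace, SimulatedDataset

TRACE_COLUMNS = ["molecule_id", "frame_index", "time_s", "intensity_donor", "intensity_acceptor"]


def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame_index": np.arange(tr.n_frames),
                    "time_s": tr.time_s,
                    "intensity_donor": tr.donor,
                    "intensity_acceptor": tr.acceptor,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> Path:
    """Write traces.tsv + manifest.json; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces_to_frame(dataset.traces).to_csv(
        out / "traces.tsv", sep="\t", index=False, float_format="%.6f"
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(dataset.manifest, fh, indent=2)
    return out


def read_dataset(in_dir: str | Path) -> tuple[list[IntensityTrace], dict]:
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    for key in ("frame_interval_s", "concentration_molar"):
        if key not in manifest:
            raise ValueError(f"manifest is missing required field {key!r}")
    df = pd.read_csv(in_dir / "traces.tsv", sep="\t")
    dt = manifest["frame_interval_s"]
    traces = []
    for mol_id, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("frame_index")
        traces.append(
            IntensityTrace(
                molecule_id=str(mol_id),
                time_s=grp["time_s"].to_numpy(),
                donor=grp["intensity_donor"].to_numpy(),
                acceptor=grp["intensity_acceptor"].to_numpy(),
                frame_interval=dt,
            )
        )
    return traces, manifest


def write_dwells(dwells: list[DwellRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "molecule_id": d.molecule_id,
                "class": d.dwell_class,
                "duration_s": d.duration_s,
                "n_frames": d.n_frames,
                "censored": d.censored,
                "from_state": d.from_state or "",
                "to_state": d.to_state or "",
            }
            for d in dwells
        ]
    ).to_csv(path, sep="\t", index=False)


def write_idealized(idealized: list[IdealizedTrajectory], path: str | Path) -> None:
    rows = []
    for ideal in idealized:
        for i, s in enumerate(ideal.states):
            rows.append(
                (ideal.molecule_id, i, STATE_LABELS[s], ideal.state_means[s])
            )
    pd.DataFrame(
        rows, columns=["molecule_id", "frame_index", "state", "state_mean"]
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_histogram(hist: HistogramSummary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_left": hist.bin_edges[:-1],
            "bin_right": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(path, index=False, float_format="%.3f")
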