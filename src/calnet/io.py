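"""Plain-text readers/writers, run configuration and pipeline orchestration.

All on-disk formats are auditable text: recordings and matrices as CSV,
edge lists and tables as TSV, ground truth and reports as JSON, networks
as GraphML.  Every file written by the pipeline starts with a provenance
header (``# key=value`` comment lines: config hash, seed, package version)
sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import CalciumRecording, CalnetError, StimulusProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ResultBundle",
    "read_recording",
    "write_recording",
    "write_ground_truth",
    "write_table",
    "write_matrix",
    "run_pipeline",
]


@dataclass(frozen=True)
class RunConfig:
    """Every tunable default of the pipeline, serializable and hashable.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    # preprocessing
    cutoff_hz: float = 0.5
    k_sd: float = 2.0
    fmin_percentile: float | None = None
    reactivity_rule: str = "mean"          # 'mean' or 'max' anchored 2-SD rule
    # connectivity
    n_surrogates: int = 1000
    q: float = 0.05
    window_seconds: float = 150.0
    n_windows: int = 5
    null_mode: str = "paired"              # or 'pooled'
    # depth-resolved analyses
    depth_step: float = 0.1
    db_step: float = 1.0
    # simulation
    seed: int = 0
    n_neurons: int = 650
    n_layers: int = 4
    p_intra: float = 0.02
    p_inter: float = 0.005
    edge_strength: float = 3.0
    subject: str = "s0"
    group: str = "control"

    def __post_init__(self) -> None:
        if not (0 < self.q < 1):
            raise CalnetError(f"q must lie in (0, 1), got {self.q}")
        if self.k_sd < 0:
            raise CalnetError("k_sd must be non-negative")
        if self.n_surrogates < 100:
            raise CalnetError("n_surrogates must be >= 100")
        if self.reactivity_rule not in ("mean", "max"):
            raise CalnetError("reactivity_rule must be 'mean' or 'max'")
        if self.null_mode not in ("paired", "pooled"):
            raise CalnetError("null_mode must be 'paired' or 'pooled'")
        if self.window_seconds <= 0 or self.n_windows < 1:
            raise CalnetError("window_seconds and n_windows must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a JSON or ``key=value`` config file; keyword overrides win."""
        path = Path(path)
        text = path.read_text()
        data: dict = {}
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            for lineno, line in enumerate(text.splitlines(), 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise CalnetError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                data[key.strip()] = json.loads(value.strip())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CalnetError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance_header(self) -> str:
        return (
            f"# calnet {__version__}\n"
            f"# config_hash={self.config_hash}\n"
            f"# seed={self.seed}\n"
        )


def write_recording(rec: CalciumRecording, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a recording as CSV: frame-time header, one row per neuron.

    Layout: comment provenance lines, then a header row
    ``neuron_id,depth,<t0>,<t1>,...`` (times in seconds) and one data row
    per neuron.  Floats use shortest round-trip repr so a read-back is
    bit-identical.
    """
    path = Path(path)
    times = np.arange(rec.n_frames) / rec.fs
    buf = _io.StringIO()
    if config is not None:
        buf.write(config.provenance_header())
    buf.write(f"# fs={rec.fs!r}\n")
    p = rec.protocol
    buf.write(
        f"# protocol={json.dumps(dataclasses.asdict(p), sort_keys=True)}\n"
    )
    buf.write("neuron_id,depth," + ",".join(repr(float(t)) for t in times) + "\n")
    for i in range(rec.n_neurons):
        row = rec.fluorescence[i]
        buf.write(
            rec.neuron_ids[i]
            + ","
            + repr(float(rec.depths[i]))
            + ","
            + ",".join(repr(float(v)) for v in row)
            + "\n"
        )
    path.write_text(buf.getvalue())


def read_recording(
    path: str | Path,
    fs: float | None = None,
    id_col: str = "neuron_id",
    depth_col: str = "depth",
) -> CalciumRecording:
    """Read a recording CSV in the dialect written by :func:`write_recording`.

    ``fs`` and the protocol are taken from the ``#`` header when present;
    ``fs`` may be overridden.  Column mapping supports deposits whose id or
    depth column is named differently.
    """
    path = Path(path)
    if not path.exists():
        raise CalnetError(f"no such file: {path}")
    header_fs: float | None = None
    protocol: StimulusProtocol | None = None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line[1:].strip()
        if stripped.startswith("fs="):
            header_fs = float(stripped[3:])
        elif stripped.startswith("protocol="):
            protocol = StimulusProtocol(**json.loads(stripped[len("protocol="):]))
    if body_start >= len(lines):
        raise CalnetError(f"{path}: empty file")
    df = pd.read_csv(
        _io.StringIO("".join(lines[body_start:])), float_precision="round_trip"
    )
    if df.empty:
        raise CalnetError(f"{path}: no neurons")
    for col in (id_col, depth_col):
        if col not in df.columns:
            raise CalnetError(f"{path}: missing required column {col!r}")
    value_cols = [c for c in df.columns if c not in (id_col, depth_col)]
    fluor = df[value_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(fluor)):
        bad = np.argwhere(~np.isfinite(fluor))[0]
        raise CalnetError(
            f"{path}: non-finite value for neuron {df[id_col].iloc[bad[0]]!r} "
            f"at frame {bad[1]} (line {body_start + 2 + bad[0]})"
        )
    use_fs = fs if fs is not None else header_fs
    if use_fs is None:
        t = np.array([float(c) for c in value_cols[:2]])
        if t.size < 2:
            raise CalnetError(f"{path}: cannot infer fs from a single frame")
        use_fs = 1.0 / (t[1] - t[0])
    if protocol is None:
        protocol = StimulusProtocol(
            fs=use_fs, total_duration=fluor.shape[1] / use_fs,
            baseline_span=min(150.0, fluor.shape[1] / use_fs / 5),
            stim_onset=fluor.shape[1] / use_fs * 0.24,
            kcl_onset=fluor.shape[1] / use_fs * 0.9,
            kcl_duration=fluor.shape[1] / use_fs * 0.04,
        )
    return CalciumRecording(
        fluorescence=fluor,
        fs=use_fs,
        depths=df[depth_col].to_numpy(dtype=float),
        protocol=protocol,
        neuron_ids=[str(x) for x in df[id_col]],
    )


def write_ground_truth(gt, path: str | Path, config: RunConfig | None = None) -> None:
    """Ground truth as JSON: edge list with strengths, parameters echoed."""
    net = gt.network
    payload = {
        "n_neurons": int(net.n_neurons),
        "depths": net.depths.tolist(),
        "module_labels": net.module_labels.tolist(),
        "edges": [
            {"i": i, "j": j, "strength": s} for (i, j), s in sorted(net.edge_params.items())
        ],
        "params": gt.params,
        "sub_seeds": gt.sub_seeds,
        "n_events_per_neuron": [int(t.size) for t in gt.event_times],
    }
    if config is not None:
        payload["provenance"] = {
            "calnet": __version__,
            "config_hash": config.config_hash,
            "seed": config.seed,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None, sep: str = "\t") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.provenance_header())
        df.to_csv(fh, sep=sep, index=False)


def write_matrix(mat: np.ndarray, path: str | Path, config: RunConfig | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.provenance_header())
        np.savetxt(fh, mat, delimiter=",")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class ResultBundle:
    out_dir: Path
    manifest: dict[str, str] = field(default_factory=dict)   # relpath -> sha256
    log_path: Path | None = None
    partial: bool = False

    def add(self, path: Path) -> None:
        self.manifest[str(path.relative_to(self.out_dir))] = _sha256(path)

    def write_manifest(self) -> Path:
        p = self.out_dir / "manifest.json"
        p.write_text(
            json.dumps(
                {"partial": self.partial, "files": self.manifest}, indent=1, sort_keys=True
            )
        )
        return p


def run_pipeline(config: RunConfig, out_dir: str | Path, recording_path: str | Path | None = None) -> ResultBundle:
    """Run simulate -> preprocess -> spectra -> connect -> metrics end to end.

    If ``recording_path`` is given that recording is analysed; otherwise a
    recording is simulated from the config.  Outputs and a checksum
    manifest are written under ``out_dir``.  Deterministic under a fixed
    config (seed included).
    """
    from . import connectivity as conn
    from . import metrics as nm
    from . import preprocess as pp
    from . import spectral as spec
    from . import synthetic as syn
    import networkx as nx

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(out_dir=out)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("calnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if recording_path is None:
            net = syn.generate_network(
                config.n_neurons, config.n_layers, config.p_intra, config.p_inter,
                seed=config.seed, edge_strength=config.edge_strength,
            )
            rec, gt = syn.simulate_recording(
                net, StimulusProtocol(), syn.DynamicsParams(), seed=config.seed + 1
            )
            write_recording(rec, out / "recording.csv", config)
            bundle.add(out / "recording.csv")
            write_ground_truth(gt, out / "ground_truth.json", config)
            bundle.add(out / "ground_truth.json")
        else:
            rec = read_recording(recording_path)

        proc = pp.process_recording(
            rec, cutoff=config.cutoff_hz, fmin_percentile=config.fmin_percentile
        )
        proc = pp.select_responsive_neurons(
            proc, k_sd=config.k_sd, rule=config.reactivity_rule
        )
        write_table(proc.selection_report, out / "selection_report.tsv", config)
        bundle.add(out / "selection_report.tsv")

        # spectral stage: basal/post band power per neuron + depth maps
        periods = spec.split_periods(proc.dff, rec.protocol, subwindow_seconds=config.window_seconds)
        spectra_rows = []
        for label in ("basal", "post"):
            block = periods[label]
            for i in range(proc.n_neurons):
                ps = spec.welch_power(block[i], rec.fs)
                spectra_rows.append(
                    {
                        "neuron_id": proc.neuron_ids[i],
                        "period": label,
                        "depth": proc.depths[i],
                        "band_power": ps.band_power,
                        "band_power_db": ps.band_power_db,
                        "retained": bool(proc.selection_mask[i]),
                    }
                )
        spectra_df = pd.DataFrame(spectra_rows)
        write_table(spectra_df, out / "spectra.tsv", config)
        bundle.add(out / "spectra.tsv")
        for label in ("basal", "post"):
            sub = spectra_df[(spectra_df["period"] == label) & spectra_df["retained"]]
            dmap = spec.depth_power_map(
                sub["band_power_db"].to_numpy(), sub["depth"].to_numpy(),
                depth_step=config.depth_step, db_step=config.db_step, period_label=label,
            )
            write_matrix(dmap.proportions, out / f"depth_power_{label}.csv", config)
            bundle.add(out / f"depth_power_{label}.csv")

        # connectivity stage on retained neurons
        keep = np.flatnonzero(proc.selection_mask)
        if keep.size < 2:
            raise CalnetError("fewer than 2 neurons retained; cannot build networks")
        traces = proc.dff[keep]
        depths = proc.depths[keep]
        windows = conn.segment_windows(
            traces.shape[1], rec.fs, config.window_seconds, config.n_windows
        )
        nets: dict[str, conn.FunctionalNetwork] = {}
        for k, label in enumerate(windows.labels):
            wc = conn.window_connectivity(
                windows.slice(traces, k),
                n_surrogates=config.n_surrogates,
                seed=config.seed + 100 + k,
                k_sd=config.k_sd,
                q=config.q,
                null_mode=config.null_mode,
                window_label=label,
            )
            net_k = conn.build_adjacency(wc, depths)
            nets[label] = net_k
            tag = label.replace(" ", "_")
            write_matrix(wc.rho, out / f"rho_{tag}.csv", config)
            bundle.add(out / f"rho_{tag}.csv")
            iu = np.triu_indices(wc.rho.shape[0], k=1)
            edges_df = pd.DataFrame(
                {
                    "i": iu[0],
                    "j": iu[1],
                    "rho": wc.rho[iu],
                    "p": wc.pvals[iu],
                    "selected": wc.fdr_mask[iu],
                }
            )
            write_table(edges_df, out / f"edges_{tag}.tsv", config)
            bundle.add(out / f"edges_{tag}.tsv")
            nx.write_graphml(net_k.to_networkx(), out / f"network_{tag}.graphml")
            bundle.add(out / f"network_{tag}.graphml")

        # metrics stage
        metric_df = nm.network_metric_rows(nets, subject=config.subject, group=config.group)
        write_table(metric_df, out / "metrics.tsv", config)
        bundle.add(out / "metrics.tsv")
        basal = nets[windows.labels[0]]
        profiles = []
        for label in windows.labels[1:]:
            prof = nm.depth_degree_profile(nets[label], basal, step=config.depth_step)
            prof.insert(0, "window", label)
            profiles.append(prof)
        write_table(pd.concat(profiles, ignore_index=True), out / "depth_degree.csv", config, sep=",")
        bundle.add(out / "depth_degree.csv")
    except Exception:
        bundle.partial = True
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
        bundle.log_path = log_path
        if log_path.exists():
            bundle.add(log_path)
        bundle.write_manifest()
    return bundle
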