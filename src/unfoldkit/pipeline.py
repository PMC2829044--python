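"""End-to-end orchestration of the unfolding analysis.

A single config drives the full analysis over a set of unfolding runs:
per-frame properties, the contacts × NPSASA and PCA landscapes with
barrier-crossing detection, conformational clustering with the
native-cluster-exit surrogate, TSE extraction and deviation map, contact
fraction series, ALF and cooperativity profiles.  Every numeric result is
persisted as plain-text tables under the output directory, stage by
stage, and summarised in a JSON report whose centrepiece is the table of
per-run crossing times by method (clustering, 2-D landscape, PCA
landscape).

Inputs are either synthetic runs (generated from the config's spec with
per-run seeds, deterministic for a given config+seed) or files (a crystal
PDB, trajectory files and a domain-partition config).  Heavy stages
(property tables, RMSD matrices) are cached: if a stage's output file
already exists in the output directory it is loaded instead of
recomputed, so deleting one stage's outputs and re-running regenerates
only that stage and its dependents.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import NoExit, classical_mds, native_cluster_exit
from .contacts import atom_contacts, contact_fraction_series
from .errors import AnalysisError, ParameterError
from .fluctuation_metrics import alf_profile, cooperativity_profile
from .landscapes import (
    NoCrossing,
    PropertyTable,
    auto_regions,
    detect_barrier_crossing,
    extract_tse,
    histogram_landscape,
    pca_landscape,
    per_frame_properties,
    tse_deviation_map,
)
from .structure_io import (
    Structure,
    Trajectory,
    load_structure,
    load_trajectory,
    parse_domain_config,
    write_structure,
    write_trajectory,
)
from .superpose import DistanceMatrix, pairwise_matrix
from .synthetic_data import SyntheticSpec, generate_unfolding_trajectory

log = logging.getLogger("unfoldkit")

__all__ = ["RunConfig", "Pipeline", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    The thresholds default to the standard analysis profile: 4.6/5.4 Å
    contact cutoffs (module constants), 3 Å cooperativity threshold, 5%
    burial threshold, 90 ps ALF window, 10 ps analysis stride, landscape
    bins of 5 native contacts × 50 Å² and 0.1 PC units, and a 19-point
    running average for smoothed series.  Each is individually
    overridable.
    """

    outdir: str = "unfoldkit_out"
    seed: int = 0
    # synthetic inputs
    synthetic: dict | None = None  # SyntheticSpec fields (seed is per-run)
    n_runs: int = 5
    # file inputs
    crystal_pdb: str | None = None
    trajectories: list[str] = field(default_factory=list)
    domain_config: dict | str | None = None
    frame_interval: float = 1.0  # ps between stored frames in input files
    # analysis parameters
    analysis_stride: float = 10.0  # ps: clustering / ALF / cooperativity
    alf_window: float = 90.0
    cooperativity_threshold: float = 3.0
    burial_threshold: float = 0.05
    smooth_window_points: int = 19
    tse_window: float = 10.0
    sasa_points: int = 240
    native_window: float | None = None  # ps of presumed-native frames; default from data

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.synthetic is None:
            if not self.crystal_pdb or not self.trajectories:
                raise ParameterError(
                    "config must give either synthetic parameters or "
                    "crystal_pdb plus trajectories"
                )
            for p in [self.crystal_pdb, *self.trajectories]:
                if not Path(p).exists():
                    raise ParameterError(f"input file does not exist: {p}")
            if self.domain_config is None:
                raise ParameterError("file inputs require a domain_config")


class Pipeline:
    """Stage-by-stage executor; see module docstring."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._trajs: list[Trajectory] | None = None
        self._crystal: Structure | None = None
        self._dp = None
        self._properties: list[PropertyTable] | None = None
        self._matrices: list[DistanceMatrix] | None = None

    # -- inputs ------------------------------------------------------------
    def load_inputs(self):
        if self._trajs is not None:
            return
        cfg = self.cfg
        if cfg.synthetic is not None:
            base = dict(cfg.synthetic)
            base.pop("seed", None)
            trajs, truths = [], []
            for k in range(cfg.n_runs):
                spec = SyntheticSpec(seed=cfg.seed + k, **base)
                traj, truth = generate_unfolding_trajectory(spec)
                trajs.append(traj)
                truths.append(truth)
                truth.save(self.out / f"truth_run{k}.json")
            self._trajs = trajs
            self._crystal = trajs[0].topology
            from .synthetic_data import make_toy_two_domain_structure

            _, self._dp = make_toy_two_domain_structure(
                SyntheticSpec(seed=cfg.seed, **base)
            )
            log.info("generated %d synthetic runs (%d frames each)",
                     len(trajs), len(trajs[0]))
        else:
            self._crystal = load_structure(cfg.crystal_pdb)
            self._dp = parse_domain_config(cfg.domain_config, self._crystal)
            self._trajs = [
                load_trajectory(p, self._crystal, stride=cfg.frame_interval,
                                frame_interval=cfg.frame_interval)
                for p in cfg.trajectories
            ]
            log.info("loaded %d trajectories", len(self._trajs))

    @property
    def trajectories(self) -> list[Trajectory]:
        self.load_inputs()
        return self._trajs

    @property
    def crystal(self) -> Structure:
        self.load_inputs()
        return self._crystal

    @property
    def partition(self):
        self.load_inputs()
        return self._dp

    # -- stages ------------------------------------------------------------
    def properties(self) -> list[PropertyTable]:
        if self._properties is None:
            tables = []
            for k, traj in enumerate(self.trajectories):
                path = self.out / f"properties_run{k}.tsv"
                if path.exists():
                    tables.append(PropertyTable.load(path))
                    continue
                pt = per_frame_properties(
                    traj, self.crystal, self.partition, sasa_points=self.cfg.sasa_points
                )
                pt.save(path)
                tables.append(pt)
                log.info("properties: run %d done (%d frames)", k, len(pt))
            self._properties = tables
        return self._properties

    def rmsd_matrices(self) -> list[DistanceMatrix]:
        if self._matrices is None:
            mats = []
            for k, traj in enumerate(self.trajectories):
                path = self.out / f"rmsd_matrix_run{k}.txt"
                if path.exists():
                    mats.append(DistanceMatrix.load(path))
                    continue
                dm = pairwise_matrix(traj, stride=self._stride(traj))
                dm.save(path)
                mats.append(dm)
                log.info("rmsd matrix: run %d done (%d x %d)", k, dm.n, dm.n)
            self._matrices = mats
        return self._matrices

    def _stride(self, traj: Trajectory) -> float:
        return max(self.cfg.analysis_stride, traj.save_interval)

    def _native_window(self, traj: Trajectory) -> float:
        if self.cfg.native_window is not None:
            return self.cfg.native_window
        # default: the first tenth of the run, at least ten strided frames
        return max(0.1 * traj.duration, 10 * self._stride(traj))

    def clustering_exits(self) -> list[float | None]:
        exits = []
        rows = []
        for k, (traj, dm) in enumerate(zip(self.trajectories, self.rmsd_matrices())):
            emb = classical_mds(dm, d=3)
            np.savetxt(
                self.out / f"embedding_run{k}.tsv",
                emb.to_table(),
                header="time_ps E1 E2 E3 (native-cluster-exit surrogate input)",
            )
            exit_t = native_cluster_exit(emb, self._native_window(traj))
            exits.append(None if isinstance(exit_t, NoExit) else exit_t)
            rows.append(exit_t)
        return exits

    def landscape_crossings(self) -> dict:
        """Both landscapes over pooled frames plus per-run crossing times."""
        tables = self.properties()
        pooled = PropertyTable.concat(tables)
        ls2d = histogram_landscape(
            pooled.df["native_residue_contacts"].to_numpy(float),
            pooled.df["npsasa"].to_numpy(float),
            5.0,
            50.0,
            labels=("native_contacts", "npsasa"),
        )
        ls2d.to_table().to_csv(self.out / "landscape_contacts_npsasa.tsv", sep="\t", index=False)
        model, lspca = pca_landscape(pooled)
        lspca.to_table().to_csv(self.out / "landscape_pca.tsv", sep="\t", index=False)
        np.savetxt(self.out / "pca_loadings.tsv", model.loadings,
                   header=" ".join(model.columns))

        out = {"landscape_2d": ls2d, "landscape_pca": lspca, "pca_model": model,
               "crossings_2d": [], "crossings_pca": []}
        for axes, key in ((("native_residue_contacts", "npsasa"), "crossings_2d"),
                          (None, "crossings_pca")):
            if axes is None:
                xs = model.scores[:, 0]
                ys = model.scores[:, 1]
                ls = lspca
            else:
                xs = pooled.df[axes[0]].to_numpy(float)
                ys = pooled.df[axes[1]].to_numpy(float)
                ls = ls2d
            native_region, nonnative_region = auto_regions(ls, xs, ys, pooled.times)
            for k in range(len(tables)):
                sel = pooled.run == k
                res = detect_barrier_crossing(
                    xs[sel], ys[sel], pooled.times[sel], native_region, nonnative_region
                )
                out[key].append(None if isinstance(res, NoCrossing) else res)
        return out

    def run(self) -> dict:
        """Execute every stage and write the JSON report."""
        cfg = self.cfg
        trajs = self.trajectories
        report: dict = {
            "version": __version__,
            "config": {k: v for k, v in asdict(cfg).items()},
            "n_runs": len(trajs),
        }
        stage = "properties"
        try:
            self.properties()
            stage = "rmsd_matrices"
            self.rmsd_matrices()
            stage = "clustering"
            exits = self.clustering_exits()
            stage = "landscapes"
            lands = self.landscape_crossings()
            stage = "tse"
            cross_pca = [c.crossing_time if c else None for c in lands["crossings_pca"]]
            cross_2d = [c.crossing_time if c else None for c in lands["crossings_2d"]]
            report["crossing_times_ps"] = {
                "conformational_clustering": exits,
                "contacts_npsasa_landscape": cross_2d,
                "pca_landscape": cross_pca,
            }
            report["pca_explained_variance"] = (
                lands["pca_model"].explained_variance_fractions[:2].tolist()
            )
            valid = [(k, t) for k, t in enumerate(cross_pca) if t is not None]
            if valid:
                tse = extract_tse(
                    [trajs[k] for k, _ in valid], [t for _, t in valid],
                    window=cfg.tse_window,
                )
                write_trajectory(
                    Trajectory(tse.topology, tse.coords,
                               np.arange(1, tse.n_members + 1)),
                    self.out / "tse_members.pdb",
                )
                devmap = tse_deviation_map(tse, self.crystal)
                per_atom = devmap[self.crystal.residue_index]
                write_structure(self.crystal, self.out / "tse_deviation_map.pdb",
                                bfactors=per_atom)
                np.savetxt(self.out / "tse_deviation_map.tsv",
                           np.column_stack([np.arange(len(devmap)), devmap]),
                           header="residue_ordinal mean_ca_deviation_A")
                report["tse"] = tse.summary(self.crystal)
            stage = "contacts"
            native = atom_contacts(self.crystal)
            for k, traj in enumerate(trajs):
                series = contact_fraction_series(traj, native, self.partition)
                series.to_tidy().to_csv(
                    self.out / f"contact_fractions_run{k}.tsv", sep="\t", index=False
                )
            stage = "metrics"
            for k, dm in enumerate(self.rmsd_matrices()):
                alf = alf_profile(dm, window=cfg.alf_window, interval=self._stride(trajs[k]))
                np.savetxt(self.out / f"alf_run{k}.tsv", alf.to_table(),
                           header="time_ps alf_A")
                coop = cooperativity_profile(dm, threshold=cfg.cooperativity_threshold)
                np.savetxt(self.out / f"cooperativity_run{k}.tsv", coop.to_table(),
                           header="time_ps count value_ps")
            stage = "figures"
            self._render_figures(lands)
        except Exception as exc:
            raise AnalysisError(f"pipeline stage {stage!r} failed: {exc}") from exc
        report_path = self.out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonify)
        log.info("report written to %s", report_path)
        return report

    def _render_figures(self, lands: dict) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for name, ls in (("landscape_contacts_npsasa", lands["landscape_2d"]),
                         ("landscape_pca", lands["landscape_pca"])):
            fig, ax = plt.subplots(figsize=(5, 4))
            v = ls.values
            ax.pcolormesh(ls.x_edges, ls.y_edges, v.T, shading="auto")
            ax.set_xlabel(ls.x_label)
            ax.set_ylabel(ls.y_label)
            ax.set_title(f"-ln(count) ({ls.n_frames} frames)")
            fig.tight_layout()
            fig.savefig(self.out / f"{name}.png", dpi=120)
            plt.close(fig)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis for a config; returns the report dict."""
    return Pipeline(config).run()
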