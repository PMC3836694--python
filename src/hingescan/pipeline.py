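"""End-to-end orchestration from a single declarative config.

Stages run in order: (simulate) -> geometry -> essential dynamics ->
torsions/clustering -> state comparison -> correlation/tally ->
(conservation) -> hinge report. Every stage writes CSV/JSON and the log
echoes every numeric parameter, so no default is silent. Reruns with the
same config produce byte-identical outputs (timestamps live only in the
log file).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from . import caller, conservation, correlation, ed, geometry, synth, torsion
from .io import SubdomainMap, Trajectory, ca_indices, make_subdomain_map, read_trajectory

STATES = synth.STATES

DEFAULT_PARAMS = {
    "top_k": 60,
    "min_runs": 4,
    "min_occupancy": 0.05,
    "match_radius": 40.0,
    "delta_occ": 0.3,
    "openness_threshold": 29.5,
    "near_cutoff": 8.0,
    "identity_min": 90.0,
    "groups_required": ["bacteria", "animals"],
    "rule": "combined90",
}

_PARAM_RANGES = {
    "top_k": (1, 100000),
    "min_runs": (1, 10000),
    "min_occupancy": (1e-9, 1.0),
    "match_radius": (1e-9, 360.0),
    "delta_occ": (1e-9, 1.0),
    "openness_threshold": (1e-9, 1e9),
    "near_cutoff": (1e-9, 1e9),
    "identity_min": (0.0, 100.0),
}

DEFAULT_SIMULATE = {
    "n_residues": 120,
    "n_runs": 5,
    "n_frames": 300,
    "noise_sd": 0.05,
    "background_kappa": 20.0,
    "openness": {s: [synth.DEFAULT_OPENNESS_MEAN[s], 1.0] for s in STATES},
    "hinges": [],
    "coupled": {},
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    params: dict
    subdomain_map: SubdomainMap | None  # None -> scaled to chain length
    simulate: dict | None = None
    trajectories: dict | None = None  # state -> list of paths
    ligands: dict | None = None  # state -> list of CSV paths (frame, x, y, z)
    conservation: dict | None = None
    echo: dict = field(default_factory=dict)  # full config as validated


def _reject_unknown(d: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def validate_config(source: str | Path | Mapping) -> RunConfig:
    """Parse and validate a config file (YAML/JSON) or mapping.

    All defaults are filled in; unknown keys are rejected; parameters are
    range-checked; referenced paths must exist.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ConfigError("config file does not contain a mapping")
    else:
        raw = dict(source)
    _reject_unknown(
        raw,
        {"seed", "out_dir", "params", "subdomain_map", "simulate", "trajectories",
         "ligands", "conservation"},
        "config",
    )
    seed = int(raw.get("seed", 0))
    out_dir = Path(raw.get("out_dir", "hingescan_out"))

    params = dict(DEFAULT_PARAMS)
    user_params = raw.get("params") or {}
    _reject_unknown(user_params, set(DEFAULT_PARAMS), "params")
    params.update(user_params)
    for key, (lo, hi) in _PARAM_RANGES.items():
        v = params[key]
        if not (lo <= float(v) <= hi):
            raise ConfigError(f"parameter {key}={v} outside [{lo}, {hi}]")

    smap_raw = raw.get("subdomain_map", "scaled")
    if smap_raw == "scaled":
        smap = None
    elif isinstance(smap_raw, str):
        smap = make_subdomain_map(smap_raw)
    else:
        smap = make_subdomain_map(
            {k: [tuple(r) for r in v] for k, v in smap_raw.items()}
        )

    simulate = raw.get("simulate")
    trajectories = raw.get("trajectories")
    if simulate is None and trajectories is None:
        raise ConfigError("config needs either 'simulate' or 'trajectories'")
    if simulate is not None:
        _reject_unknown(simulate, set(DEFAULT_SIMULATE), "simulate")
        filled = {k: simulate.get(k, v) for k, v in DEFAULT_SIMULATE.items()}
        if filled["n_frames"] < 10:
            raise ConfigError("simulate.n_frames must be >= 10")
        if filled["n_runs"] < 1:
            raise ConfigError("simulate.n_runs must be >= 1")
        simulate = filled
    if trajectories is not None:
        for state, paths in trajectories.items():
            if state not in STATES:
                raise ConfigError(f"unknown state {state!r} in trajectories")
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"trajectory file not found: {p}")
    ligands = raw.get("ligands")
    if ligands is not None:
        for state, paths in ligands.items():
            if state not in STATES:
                raise ConfigError(f"unknown state {state!r} in ligands")
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"ligand series file not found: {p}")
    cons = raw.get("conservation")
    if cons is not None:
        _reject_unknown(cons, {"msa", "groups"}, "conservation")
        for key in ("msa", "groups"):
            if key in cons and not Path(cons[key]).exists():
                raise ConfigError(f"conservation file not found: {cons[key]}")

    echo = {
        "seed": seed,
        "out_dir": str(out_dir),
        "params": params,
        "subdomain_map": smap_raw if isinstance(smap_raw, str) else dict(smap_raw),
        "simulate": simulate,
        "trajectories": trajectories,
        "ligands": ligands,
        "conservation": cons,
    }
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        params=params,
        subdomain_map=smap,
        simulate=simulate,
        trajectories=trajectories,
        ligands=ligands,
        conservation=cons,
        echo=echo,
    )


def _hinges_from_config(hinges: list) -> tuple[synth.HingePlant, ...]:
    out = []
    for h in hinges:
        _reject_unknown(h, {"residue", "mode1", "mode2", "occupancy2", "kappa"}, "hinge")
        out.append(
            synth.HingePlant(
                residue=int(h["residue"]),
                mode1=tuple(h["mode1"]),
                mode2=tuple(h["mode2"]),
                occupancy2=h.get("occupancy2", 0.5),
                kappa=float(h.get("kappa", 20.0)),
            )
        )
    return tuple(out)


def simulate_ensembles(cfg: RunConfig):
    """Generate all three state ensembles from the simulate block.

    State i uses base seed ``seed + 1000*i``; run k of a state adds k.
    Returns (ensembles, truth) with ensembles[state] = list of
    (Trajectory, ligand series).
    """
    sim = cfg.simulate
    hinges = _hinges_from_config(sim["hinges"])
    coupled = {int(r): float(w) for r, w in (sim["coupled"] or {}).items()}
    smap = cfg.subdomain_map or synth.scaled_subdomain_map(sim["n_residues"])
    ensembles = {}
    truth = None
    for i, state in enumerate(STATES):
        mean, sd = sim["openness"][state]
        spec = synth.PlantSpec(
            n_residues=sim["n_residues"],
            state=state,
            openness_mean=float(mean),
            openness_sd=float(sd),
            hinge_residues=hinges,
            coupled_residues=coupled,
            noise_sd=float(sim["noise_sd"]),
            background_kappa=float(sim["background_kappa"]),
            subdomain_map=smap,
            seed=cfg.seed + 1000 * i,
        )
        runs, t = synth.generate_ensemble(spec, sim["n_runs"], sim["n_frames"])
        ensembles[state] = runs
        if truth is None:
            truth = t
        else:
            truth.openness.update(t.openness)
    return ensembles, truth


def _load_ensembles(cfg: RunConfig):
    ensembles = {}
    for state, paths in (cfg.trajectories or {}).items():
        runs = []
        for k, p in enumerate(paths):
            traj = read_trajectory(p, label=f"{state}_run{k + 1}")
            lig = None
            if cfg.ligands and state in cfg.ligands and k < len(cfg.ligands[state]):
                df = pd.read_csv(cfg.ligands[state][k])
                lig = df[["x", "y", "z"]].to_numpy(dtype=float)
            runs.append((traj, lig))
        ensembles[state] = runs
    return ensembles, None


def _ligand_point_distances(traj: Trajectory, point: np.ndarray, cutoff: float) -> pd.DataFrame:
    """Per-residue min distance from topology atoms to one pseudo-site."""
    topo = traj.topology
    rows = []
    for r in np.unique(topo.res_numbers):
        idx = np.nonzero(topo.res_numbers == r)[0]
        d = float(cdist(topo.coords[idx], point[None, :]).min())
        rows.append({"residue": int(r), "min_distance": d, "near": d < cutoff})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the output directory."""
    t0 = time.time()
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"hingescan pipeline, seed={cfg.seed}"]
    log_lines.append("parameters: " + json.dumps(cfg.params, sort_keys=True))

    stage = "simulate"
    try:
        if cfg.simulate is not None:
            ensembles, truth = simulate_ensembles(cfg)
            if truth is not None:
                (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
        else:
            ensembles, truth = _load_ensembles(cfg)
        states = [s for s in STATES if s in ensembles]
        any_traj = ensembles[states[0]][0][0]
        n_res = int(np.unique(any_traj.topology.res_numbers).size)
        smap = cfg.subdomain_map or synth.scaled_subdomain_map(n_res)

        stage = "geometry"
        open_rows = []
        for state in states:
            for k, (traj, _) in enumerate(ensembles[state]):
                series = geometry.openness_series(
                    traj, smap, threshold=cfg.params["openness_threshold"]
                )
                open_rows.append(
                    {
                        "state": state,
                        "run": k + 1,
                        "n_frames": traj.n_frames,
                        "mean_A": series.mean,
                        "sd_A": series.sd,
                        "label": series.label,
                    }
                )
        openness_df = pd.DataFrame(open_rows)
        openness_df.to_csv(out / "openness.csv", index=False)

        stage = "essential_dynamics"
        ed_rows = []
        for state in states:
            ca = ca_indices(ensembles[state][0][0].topology)
            combined = ed.combine_runs([t for t, _ in ensembles[state]], ca)
            res = ed.compute_ed(combined, ca, refit=False)
            frac = res.cumulative_fractions
            for m in range(min(25, res.eigenvalues.size)):
                ed_rows.append(
                    {
                        "state": state,
                        "mode": m + 1,
                        "eigenvalue_A2": float(res.eigenvalues[m]),
                        "cumulative_fraction": float(frac[m]),
                    }
                )
        pd.DataFrame(ed_rows).to_csv(out / "ed_eigen.csv", index=False)

        stage = "torsions"
        clusterings = {}
        cluster_rows = []
        for state in states:
            frames = np.concatenate([t.frames for t, _ in ensembles[state]], axis=0)
            traj_all = Trajectory(ensembles[state][0][0].topology, frames, label=state)
            series = torsion.compute_dihedrals(traj_all)
            clusterings[state] = torsion.cluster_all_residues(
                series, min_occupancy=cfg.params["min_occupancy"]
            )
            for r, cl in sorted(clusterings[state].items()):
                for ci, c in enumerate(cl.clusters):
                    cluster_rows.append(
                        {
                            "state": state,
                            "residue": r,
                            "cluster_id": ci,
                            "phi_center": round(c.phi, 2),
                            "psi_center": round(c.psi, 2),
                            "occupancy": round(c.occupancy, 4),
                        }
                    )
        pd.DataFrame(cluster_rows).to_csv(out / "clusters.csv", index=False)
        multimodal = set()
        for state in states:
            multimodal |= torsion.multimodal_residues(clusterings[state])

        stage = "state_comparison"
        shift_rows = []
        shifted: dict[int, bool] = {}
        pairs = [(a, b) for i, a in enumerate(states) for b in states[i + 1 :]]
        for a, b in pairs:
            common = set(clusterings[a]) & set(clusterings[b])
            calls = torsion.compare_states(
                {r: clusterings[a][r] for r in common},
                {r: clusterings[b][r] for r in common},
                match_radius=cfg.params["match_radius"],
                delta_occ=cfg.params["delta_occ"],
            )
            for r, call in sorted(calls.items()):
                if call.shifted:
                    shifted[r] = True
                shift_rows.append(
                    {
                        "state_a": a,
                        "state_b": b,
                        "residue": r,
                        "shifted": call.shifted,
                        "criterion": call.criterion,
                    }
                )
        pd.DataFrame(shift_rows).to_csv(out / "state_shifts.csv", index=False)

        stage = "correlation"
        top_lists = []
        ligand_mean = None
        for state in states:
            if state == "apo":
                continue  # no nucleotide site in the apo ensemble
            for k, (traj, lig) in enumerate(ensembles[state]):
                if lig is None:
                    continue
                ca = ca_indices(traj.topology)
                cm = correlation.dcc_matrix(traj, ca, [lig], ["nucleotide"])
                top = correlation.rank_by_ligand(cm, k=int(cfg.params["top_k"]))
                top_lists.append(top)
                ligand_mean = lig.mean(axis=0) if ligand_mean is None else ligand_mean
                pd.DataFrame({"rank": np.arange(1, len(top) + 1), "residue": top}).to_csv(
                    out / f"top_correlated_{state}_run{k + 1}.csv", index=False
                )
        tally = None
        if top_lists:
            tally = correlation.tally_runs(
                top_lists, min_runs=int(cfg.params["min_runs"])
            )
            tally.counts.to_csv(out / "tally.csv", index=False)
        counts = (
            {int(r): int(c) for r, c in zip(tally.counts["residue"], tally.counts["count"])}
            if tally
            else {}
        )

        stage = "conservation"
        profile = None
        if cfg.conservation is not None:
            aln = conservation.read_alignment(
                cfg.conservation["msa"], cfg.conservation.get("groups")
            )
            profile = conservation.conservation_profile(aln)
            profile.to_csv(out / "conservation.csv", index=False)

        stage = "report"
        distances = None
        if ligand_mean is not None:
            distances = _ligand_point_distances(
                any_traj, ligand_mean, cfg.params["near_cutoff"]
            )
        universe = sorted(int(r) for r in np.unique(any_traj.topology.res_numbers))
        report = caller.build_report(
            universe=universe,
            multimodal=multimodal,
            shifted=shifted,
            tally_counts=counts,
            min_runs=int(cfg.params["min_runs"]),
            conservation_profile=profile,
            distances=distances,
            identity_min=float(cfg.params["identity_min"]),
            groups_required=tuple(cfg.params["groups_required"]),
            parameters={
                "top_k": cfg.params["top_k"],
                "match_radius": cfg.params["match_radius"],
                "delta_occ": cfg.params["delta_occ"],
                "min_occupancy": cfg.params["min_occupancy"],
                "openness_threshold": cfg.params["openness_threshold"],
                "near_cutoff": cfg.params["near_cutoff"],
                "seed": cfg.seed,
            },
        )
        candidates = caller.select_candidates(report, rule=cfg.params["rule"])
        groups = caller.group_candidates(report, candidates)
        report.table.to_csv(out / "report.csv", index=False)
        payload = {
            "parameters": report.parameters,
            "openness": open_rows,
            "multimodal": sorted(multimodal),
            "state_shifted": sorted(r for r, v in shifted.items() if v),
            "tally_significant": sorted(tally.significant_residues()) if tally else [],
            "conservation": (
                "evaluated" if profile is not None else "not evaluated"
            ),
            "candidates": candidates,
            "candidate_groups": {k: sorted(v) for k, v in groups.items()},
        }
        (out / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # noqa: BLE001 - halt with the stage name
        raise StageError(stage, str(exc)) from exc

    log_lines.append(f"stages complete in {time.time() - t0:.1f} s")
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
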