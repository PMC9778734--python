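"""Configuration validation and the two chained workflows.

``cmd_projection``: trajectory → CV extraction → direct ΔG projections →
Gromos clustering → next-round seed suggestion.

``umbrella_wham``: window manifest → equilibration discard → WHAM →
direct/reverse convergence check → reweighted projections → optional
puckering summary.

Every run writes a ``provenance.json`` carrying the config hash, seed and
parameters needed to regenerate the outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .collective_variables import (
    contact_occupancy,
    d_actsite,
    d_react,
    nearest_solvent_distance,
    pair_distance,
    reaction_coordinate,
)
from .conformations import ConformationSet, gromos_cluster, select_seed
from .constants import DEFAULT_TEMPERATURE
from .errors import ValidationError
from .free_energy import (
    UmbrellaWindow,
    convergence_check,
    direct_projection,
    equilibration_discard,
    pool_windows,
    reweighted_projection,
    wham_solve,
)
from .io import (
    read_cv_table,
    read_trajectory,
    resolve_selection,
    write_cv_table,
    write_profile,
)
from .puckering import pucker_series
from .series import CVSeries

log = logging.getLogger("glycopmf")

_COMPOSITES = {
    "reaction_coordinate": (reaction_coordinate, 2),
    "d_actsite": (d_actsite, 3),
    "d_react": (d_react, 3),
}


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such config file: {path}")
    with path.open() as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return config


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def validate_config(config: dict, workflow: str | None = None) -> str:
    """Check structural validity before any compute; returns the workflow name."""
    workflow = workflow or config.get("workflow")
    if workflow not in ("cmd_projection", "umbrella_wham"):
        raise ValidationError(
            f"workflow must be cmd_projection or umbrella_wham, got {workflow!r}"
        )
    temperature = config.get("temperature", DEFAULT_TEMPERATURE)
    if not temperature > 0:
        raise ValidationError("temperature must be positive")

    if workflow == "cmd_projection":
        if "trajectory" not in config:
            raise ValidationError("cmd_projection config needs a 'trajectory' path")
        if not Path(config["trajectory"]).exists():
            raise ValidationError(f"trajectory file not found: {config['trajectory']}")
        cv_defs = config.get("cvs", {})
        defined = set(cv_defs)
        selections = set(config.get("selections", {}))
        for name, cv in cv_defs.items():
            if "formula" in cv:
                formula = cv["formula"]
                if formula not in _COMPOSITES:
                    raise ValidationError(f"CV {name!r}: unknown formula {formula!r}")
                _, arity = _COMPOSITES[formula]
                args = cv.get("args", [])
                if len(args) != arity:
                    raise ValidationError(f"CV {name!r}: {formula} takes {arity} arguments")
                missing = [a for a in args if a not in defined]
                if missing:
                    raise ValidationError(f"CV {name!r} references undefined CVs {missing}")
            else:
                for side in ("a", "b"):
                    if side not in cv:
                        raise ValidationError(f"CV {name!r}: missing selection {side!r}")
                    ref = cv[side]
                    if isinstance(ref, str) and ref not in selections:
                        raise ValidationError(f"CV {name!r} references undefined selection {ref!r}")
        for proj in config.get("projections", []):
            for axis in proj.get("axes", []):
                if axis not in defined:
                    raise ValidationError(f"projection references undefined CV {axis!r}")
        cluster = config.get("cluster")
        if cluster is not None and isinstance(cluster.get("selection"), str):
            if cluster["selection"] not in selections:
                raise ValidationError(
                    f"cluster references undefined selection {cluster['selection']!r}"
                )
    else:
        window_entries = config.get("windows")
        if not window_entries:
            raise ValidationError("umbrella_wham config needs a nonempty 'windows' list")
        for i, entry in enumerate(window_entries):
            for key in ("file", "center", "force_constant"):
                if key not in entry:
                    raise ValidationError(f"window {i}: missing {key!r}")
            if not Path(entry["file"]).exists():
                raise ValidationError(f"window {i}: file not found: {entry['file']}")
    return workflow


def _selection_of(traj, config, ref, label):
    if isinstance(ref, str):
        return resolve_selection(traj, config.get("selections", {})[ref], ref)
    return resolve_selection(traj, ref, label)


def compute_cv_series(traj, config) -> CVSeries:
    """Evaluate configured CVs frame by frame; composites resolve after distances."""
    temperature = config.get("temperature", DEFAULT_TEMPERATURE)
    cv_defs = config.get("cvs", {})
    columns: dict[str, np.ndarray] = {}
    for name, cv in cv_defs.items():
        if "formula" in cv:
            continue
        sel_a = _selection_of(traj, config, cv["a"], f"{name}.a")
        sel_b = _selection_of(traj, config, cv["b"], f"{name}.b")
        mode = cv.get("mode", "single")
        values = np.empty(traj.n_frames)
        if mode == "nearest_solvent":
            for i in range(traj.n_frames):
                values[i], _ = nearest_solvent_distance(traj.coords[i], sel_a, sel_b)
        else:
            for i in range(traj.n_frames):
                values[i] = pair_distance(traj.coords[i], sel_a, sel_b, mode=mode)
        columns[name] = values
    for name, cv in cv_defs.items():
        if "formula" not in cv:
            continue
        func, _ = _COMPOSITES[cv["formula"]]
        columns[name] = func(*[columns[a] for a in cv["args"]])
    if not columns:
        raise ValidationError("no CVs defined")
    labels = list(columns)
    values = np.column_stack([columns[label] for label in labels])
    return CVSeries(times=np.asarray(traj.times, dtype=float), values=values,
                    labels=labels, temperature=temperature)


def _write_provenance(out_dir: Path, config: dict, workflow: str, outputs: dict) -> None:
    provenance = {
        "package": "glycopmf",
        "version": __version__,
        "workflow": workflow,
        "config_sha256": _config_hash(config),
        "seed": config.get("seed"),
        "temperature": config.get("temperature", DEFAULT_TEMPERATURE),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))


def run_pipeline(config: dict, workflow: str | None = None, out_dir=None) -> dict:
    """Execute one of the two workflows; returns a manifest of output paths."""
    workflow = validate_config(config, workflow)
    out_dir = Path(out_dir or config.get("out", "glycopmf_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if workflow == "cmd_projection":
        log.info("reading trajectory %s", config["trajectory"])
        traj = read_trajectory(config["trajectory"], fmt=config.get("format"))
        series = compute_cv_series(traj, config)
        outputs["cv_table"] = out_dir / "cvs.tsv"
        write_cv_table(series, outputs["cv_table"])

        for proj in config.get("projections", []):
            axes = proj["axes"]
            profile = direct_projection(series, axes=axes, n_bins=proj.get("bins", "auto"))
            name = "profile_" + "_".join(axes) + ".tsv"
            outputs[name] = out_dir / name
            write_profile(profile, outputs[name])

        for occ in config.get("contacts", []):
            frac, count, total = contact_occupancy(
                series.column(occ["cv"]), occ.get("cutoff", 3.5))
            path = out_dir / f"contact_{occ['cv']}.json"
            path.write_text(json.dumps(
                {"cv": occ["cv"], "cutoff": occ.get("cutoff", 3.5),
                 "fraction": frac, "count": count, "total": total}, indent=2))
            outputs[f"contact_{occ['cv']}"] = path

        cluster_cfg = config.get("cluster")
        if cluster_cfg is not None:
            sel = _selection_of(traj, config, cluster_cfg.get("selection", {"heavy": True}),
                                "cluster")
            conf_set = ConformationSet(coords=traj.coords[:, sel.indices],
                                       times=np.asarray(traj.times, dtype=float),
                                       selection_label=sel.label)
            result = gromos_cluster(conf_set, cutoff=cluster_cfg.get("cutoff", 1.2),
                                    fit=cluster_cfg.get("fit", True))
            outputs["clusters"] = out_dir / "clusters.tsv"
            with outputs["clusters"].open("w") as fh:
                fh.write("# frame\ttime_ps\tcluster\tis_centroid\n")
                for i in range(len(conf_set)):
                    is_c = int(i in result.centroids)
                    fh.write(f"{i}\t{conf_set.times[i]:.17g}\t{result.assignments[i]}\t{is_c}\n")
            seed_frame = select_seed(
                result, conf_set, conf_set.coords[cluster_cfg.get("start_frame", 0)],
                occupancy_min=cluster_cfg.get("occupancy_min", 10.0))
            summary = {
                "occupancies_percent": result.occupancies.tolist(),
                "centroid_frames": result.centroids,
                "suggested_seed_frame": seed_frame,
            }
            outputs["cluster_summary"] = out_dir / "cluster_summary.json"
            outputs["cluster_summary"].write_text(json.dumps(summary, indent=2))
    else:
        temperature = config.get("temperature", DEFAULT_TEMPERATURE)
        windows = []
        for entry in config["windows"]:
            series = read_cv_table(entry["file"], temperature=temperature)
            windows.append(UmbrellaWindow(
                center=float(entry["center"]),
                force_constant=float(entry["force_constant"]),
                series=series,
                biased_label=entry.get("biased_label"),
            ))
        t_eq = config.get("t_eq", 2.0)
        log.info("discarding first %.3g ps of each of %d windows", t_eq, len(windows))
        windows = [equilibration_discard(w, t_eq) for w in windows]

        n_bins = config.get("bins", 200)
        solution, pmf = wham_solve(windows, n_bins=n_bins,
                                   tolerance=config.get("wham_tolerance", 1e-7))
        outputs["pmf"] = out_dir / "pmf.tsv"
        write_profile(pmf, outputs["pmf"])
        outputs["window_offsets"] = out_dir / "window_offsets.tsv"
        with outputs["window_offsets"].open("w") as fh:
            fh.write("# center\tforce_constant\tF_j_kcal_mol\tn_samples\n")
            for w, fj, nj in zip(windows, solution.f, solution.n_samples_per_window):
                fh.write(f"{w.center:.17g}\t{w.force_constant:.17g}\t{fj:.17g}\t{int(nj)}\n")

        conv_cfg = config.get("convergence", {})
        conv_report = {}
        for scheme in ("direct", "reverse"):
            report = convergence_check(
                windows, scheme=scheme,
                n_blocks=conv_cfg.get("n_blocks", 5),
                tolerance=conv_cfg.get("tolerance", 1.0),
                n_bins=n_bins)
            conv_report[scheme] = {
                "fractions": report.fractions,
                "deviations": report.deviations,
                "converged": report.converged,
            }
        outputs["convergence"] = out_dir / "convergence.json"
        outputs["convergence"].write_text(json.dumps(conv_report, indent=2))

        pooled = pool_windows(windows)
        weights = solution.sample_weights
        outputs["weights"] = out_dir / "weights.tsv"
        with outputs["weights"].open("w") as fh:
            fh.write("# sample\tweight\n")
            for i, w in enumerate(weights):
                fh.write(f"{i}\t{w:.17g}\n")

        for proj in config.get("projections", []):
            axes = proj["axes"]
            profile = reweighted_projection(pooled, weights, axes=axes,
                                            n_bins=proj.get("bins", "auto"))
            name = "profile_" + "_".join(axes) + ".tsv"
            outputs[name] = out_dir / name
            write_profile(profile, outputs[name])

        pucker_cfg = config.get("pucker")
        if pucker_cfg is not None:
            traj = read_trajectory(pucker_cfg["trajectory"], fmt=pucker_cfg.get("format"))
            sel = resolve_selection(traj, pucker_cfg.get("ring_atoms",
                                    {"atom_name": ["O5", "C1", "C2", "C3", "C4", "C5"]}),
                                    "ring")
            states, occupancy = pucker_series(traj.ring_geometries(sel))
            outputs["pucker"] = out_dir / "pucker.tsv"
            with outputs["pucker"].open("w") as fh:
                fh.write("# frame\ttime_ps\tQ\tphi\ttheta\tconformer\n")
                for i, st in enumerate(states):
                    fh.write(f"{i}\t{traj.times[i]:.17g}\t{st.Q:.17g}\t"
                             f"{st.phi:.17g}\t{st.theta:.17g}\t{st.conformer}\n")
            outputs["pucker_occupancy"] = out_dir / "pucker_occupancy.json"
            outputs["pucker_occupancy"].write_text(json.dumps(occupancy, indent=2))

    _write_provenance(out_dir, config, workflow, outputs)
    outputs["provenance"] = out_dir / "provenance.json"
    return {k: str(v) for k, v in outputs.items()}
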