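"""End-to-end orchestration of the three analyses.

A single config drives (1) intrinsic dynamics — GNM/ANM modes, mobility
and B-factor profiles, hinges, mode correspondence, and overlap of modes
with an open->closed deformation; (2) communication — affinity/Markov
models, hitting-time profiles, domain-pair statistics, difference maps and
optimal pathways; (3) family comparison — subsystem normal modes against a
reference structure with the mean slow-mode overlap summary.  Reports are
CSV tables plus a JSON run manifest; every run is reproducible from
(config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .communication import (build_affinity, build_markov, decompose_hitting,
                            group_path_stats, hitting_times,
                            mean_receive_time, shortest_path)
from .deformation import (cumulative_overlap, deformation_vector,
                          generate_conformers, overlap, superpose,
                          apply_transform)
from .elastic_models import (DEFAULT_ANM_CUTOFF, DEFAULT_GNM_CUTOFF,
                             build_hessian, build_kirchhoff, decompose,
                             find_hinges, map_gnm_to_anm, msf_profile,
                             predict_bfactors)
from .structure_io import (AlignmentMap, CoarseModel, build_coarse_model,
                           read_alignment_map, read_structure_file,
                           write_coarse_pdb)
from .subsystem import (effective_hessian, family_overlap_summary,
                        mode_correlation_matrix, subsystem_modes)
from .synthetic_data import ToySpec, deform_toy, make_toy

logger = logging.getLogger("aakdyn.pipeline")

__all__ = ["AnalysisConfig", "run_intrinsic_dynamics", "run_communication",
           "run_family_comparison"]


@dataclass
class StructureSource:
    """Either a PDB file path or an inline synthetic-toy specification.

    ``deform`` (toys only) applies :func:`aakdyn.synthetic_data.deform_toy`
    after generation, e.g. ``{"mode": 1, "amplitude": 1.0}``, producing a
    synthetic "closed" state with a known deformation direction.
    """

    path: str | None = None
    toy: dict | None = None
    deform: dict | None = None
    include_ligands: bool = False
    chains: list[str] | None = None

    def load(self) -> CoarseModel:
        if (self.path is None) == (self.toy is None):
            raise ValueError("give exactly one of 'path' or 'toy'")
        if self.path is not None:
            structure = read_structure_file(self.path)
            return build_coarse_model(
                structure, include_ligands=self.include_ligands,
                chains=self.chains,
            )
        model = make_toy(ToySpec(**self.toy))
        if self.deform:
            model = deform_toy(model, **self.deform)
        return model


@dataclass
class AnalysisConfig:
    structures: dict[str, StructureSource]
    gnm_cutoff: float = DEFAULT_GNM_CUTOFF
    anm_cutoff: float = DEFAULT_ANM_CUTOFF
    affinity_threshold: float = 4.0
    n_modes: int = 10
    conformer_rmsd: float = 1.0
    hitting_convention: str = "receive"
    groups: dict[str, list[int]] = field(default_factory=dict)
    group_pairs: list[tuple[str, str]] = field(default_factory=list)
    pathways: list[tuple[int, int]] = field(default_factory=list)
    alignment_maps: dict[str, str] = field(default_factory=dict)
    subsystems: dict[str, list[int]] = field(default_factory=dict)
    outdir: str = "aakdyn_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        raw["structures"] = {
            name: StructureSource(**src)
            for name, src in raw.get("structures", {}).items()
        }
        raw["group_pairs"] = [tuple(p) for p in raw.get("group_pairs", [])]
        raw["pathways"] = [tuple(p) for p in raw.get("pathways", [])]
        return cls(**raw)

    def params(self) -> dict:
        return {
            "gnm_cutoff": self.gnm_cutoff,
            "anm_cutoff": self.anm_cutoff,
            "affinity_threshold": self.affinity_threshold,
            "n_modes": self.n_modes,
            "conformer_rmsd": self.conformer_rmsd,
            "hitting_convention": self.hitting_convention,
            "seed": self.seed,
        }


def _outdir(config: AnalysisConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _manifest(config: AnalysisConfig, stage: str, outputs: list[str]) -> None:
    out = _outdir(config) / f"manifest_{stage}.json"
    payload = {
        "stage": stage,
        "package_version": __version__,
        "parameters": config.params(),
        "structures": {
            name: (src.path if src.path else {"toy": src.toy})
            for name, src in config.structures.items()
        },
        "outputs": outputs,
    }
    out.write_text(json.dumps(payload, indent=2, default=str))


def _load_alignment(config: AnalysisConfig, key: str,
                    n_a: int, n_b: int) -> AlignmentMap:
    if key in config.alignment_maps:
        with open(config.alignment_maps[key]) as fh:
            return read_alignment_map(fh.read(), n_a, n_b)
    if n_a != n_b:
        raise ValueError(
            f"no alignment map '{key}' and node counts differ ({n_a}, {n_b})"
        )
    return AlignmentMap.identity(n_a)


def run_intrinsic_dynamics(config: AnalysisConfig) -> dict:
    """GNM/ANM analysis of the open form, plus overlap of the open form's
    ANM modes with the open->closed deformation when a closed structure is
    configured."""
    out = _outdir(config)
    report: dict = {}
    outputs: list[str] = []
    if "open" not in config.structures:
        raise ValueError("intrinsic dynamics needs an 'open' structure")
    model = config.structures["open"].load()
    logger.info("intrinsic dynamics: open form, N=%d nodes", model.n_nodes)

    gnm = decompose(build_kirchhoff(model, config.gnm_cutoff))
    anm = decompose(build_hessian(model, config.anm_cutoff))
    msf = msf_profile(gnm)
    n_modes = min(config.n_modes, gnm.n_modes, anm.n_modes)

    table = pd.DataFrame({"label": model.labels, "msf": msf})
    b_exp = model.b_factors
    if np.isfinite(b_exp).sum() >= 3 and np.ptp(b_exp[np.isfinite(b_exp)]) > 0:
        b_pred, corr = predict_bfactors(msf, b_exp)
        table["b_experimental"] = b_exp
        table["b_predicted"] = b_pred
        report["bfactor_correlation"] = corr
    for k in range(1, n_modes + 1):
        table[f"gnm_mode{k}_mobility"] = msf_profile(gnm, [k])
    path = out / "intrinsic_profile.csv"
    table.to_csv(path, index=False)
    outputs.append(str(path))

    hinges = {
        k: find_hinges(gnm.mode(k), chains=model.chains)
        for k in range(1, min(3, gnm.n_modes) + 1)
    }
    report["hinges"] = {
        k: [model.labels[i] for i in idx] for k, idx in hinges.items()
    }
    report["hinge_indices"] = hinges

    corr_map = map_gnm_to_anm(gnm, anm, n_modes)
    pd.DataFrame(
        corr_map,
        index=[f"gnm{k + 1}" for k in range(corr_map.shape[0])],
        columns=[f"anm{k + 1}" for k in range(corr_map.shape[1])],
    ).to_csv(out / "gnm_anm_map.csv")
    outputs.append(str(out / "gnm_anm_map.csv"))
    report["gnm_anm_map"] = corr_map

    if "closed" in config.structures:
        closed = config.structures["closed"].load()
        key = "open:closed"
        mapping = _load_alignment(config, key, model.n_nodes, closed.n_nodes)
        deform = deformation_vector(model, closed, mapping)
        m_max = min(50, anm.n_modes)
        cos = [overlap(anm.mode(k), deform) for k in range(1, m_max + 1)]
        co = cumulative_overlap(anm, deform, m_max)
        pd.DataFrame(
            {"mode": np.arange(1, m_max + 1), "cos": cos, "co": co}
        ).to_csv(out / "overlap_open_closed.csv", index=False)
        outputs.append(str(out / "overlap_open_closed.csv"))
        report["deformation_rmsd"] = deform.rmsd
        report["cumulative_overlap"] = co
    else:
        logger.info("no closed structure configured; overlap section skipped")

    for k in (1,):
        plus, minus = generate_conformers(
            model, anm, k, target_rmsd=config.conformer_rmsd
        )
        for tag, coords in (("plus", plus), ("minus", minus)):
            p = out / f"conformer_mode{k}_{tag}.pdb"
            write_coarse_pdb(model, coords.ravel(), p)
            outputs.append(str(p))

    _manifest(config, "intrinsic", outputs)
    report["outputs"] = outputs
    return report


def run_communication(config: AnalysisConfig) -> dict:
    """Hitting-time analysis for every configured state, group statistics,
    optimal pathways, and the open-minus-last-state cross-contribution
    difference map when states share a node labelling."""
    out = _outdir(config)
    report: dict = {}
    outputs: list[str] = []
    if not config.structures:
        raise ValueError("communication needs at least one structure")

    results = {}
    profile_table = {}
    for name, src in config.structures.items():
        model = src.load()
        aff = build_affinity(model, config.affinity_threshold)
        res = hitting_times(aff)
        results[name] = (model, aff, res)
        profile = mean_receive_time(res, config.hitting_convention)
        profile_table.setdefault("label", model.labels)
        profile_table[f"{name}_mean_hitting"] = profile
        np.savetxt(out / f"hitting_{name}.csv", res.hitting, delimiter=",")
        outputs.append(str(out / f"hitting_{name}.csv"))
        logger.info("communication: state %s, N=%d", name, model.n_nodes)

    n_ref = len(next(iter(results.values()))[0].labels)
    if all(len(m.labels) == n_ref for m, _, _ in results.values()):
        pd.DataFrame(profile_table).to_csv(
            out / "mean_hitting_profiles.csv", index=False
        )
        outputs.append(str(out / "mean_hitting_profiles.csv"))

    group_rows = []
    for name, (model, aff, res) in results.items():
        for ga, gb in config.group_pairs:
            mean, sd = group_path_stats(
                res, config.groups[ga], config.groups[gb]
            )
            group_rows.append(
                {"state": name, "group_a": ga, "group_b": gb,
                 "mean_hitting": mean, "sd_hitting": sd}
            )
    if group_rows:
        pd.DataFrame(group_rows).to_csv(
            out / "group_path_stats.csv", index=False
        )
        outputs.append(str(out / "group_path_stats.csv"))
        report["group_stats"] = group_rows

    path_rows = []
    for name, (model, aff, res) in results.items():
        markov = build_markov(aff)
        for s, t in config.pathways:
            nodes, cost = shortest_path(markov, s, t)
            path_rows.append(
                {"state": name, "source": model.labels[s],
                 "target": model.labels[t],
                 "path": "->".join(model.labels[i] for i in nodes),
                 "cost": cost}
            )
    if path_rows:
        pd.DataFrame(path_rows).to_csv(out / "pathways.csv", index=False)
        outputs.append(str(out / "pathways.csv"))
        report["pathways"] = path_rows

    names = list(results)
    if len(names) >= 2:
        first, last = names[0], names[-1]
        aff_a, aff_b = results[first][1], results[last][1]
        if aff_a.n_nodes == aff_b.n_nodes:
            diff = decompose_hitting(aff_a, aff_b)
            np.savetxt(
                out / f"cross_diff_{first}_minus_{last}.csv", diff,
                delimiter=",",
            )
            outputs.append(str(out / f"cross_diff_{first}_minus_{last}.csv"))
            report["cross_difference"] = diff
        else:
            logger.info(
                "difference map skipped: %s and %s differ in node count",
                first, last,
            )

    report["mean_profiles"] = {
        name: mean_receive_time(res, config.hitting_convention)
        for name, (_, _, res) in results.items()
    }
    _manifest(config, "communication", outputs)
    report["outputs"] = outputs
    return report


def run_family_comparison(config: AnalysisConfig, reference: str = "ref",
                          other: str = "other") -> dict:
    """Slow-mode conservation between a reference structure and a family
    member: modes from the (optionally environment-coupled) ANM Hessians
    after rigid superposition over mapped C-alphas, the n x n |cos| matrix,
    and the mean CO(m) summary in percent."""
    out = _outdir(config)
    outputs: list[str] = []
    model_a = config.structures[reference].load()
    model_b = config.structures[other].load()
    mapping = _load_alignment(
        config, f"{reference}:{other}", model_a.n_nodes, model_b.n_nodes
    )
    rot, trans, rmsd = superpose(model_a.coords, model_b.coords, mapping)
    model_b = model_b.with_coords(apply_transform(model_b.coords, rot, trans))
    logger.info("family comparison: superposition RMSD %.3f A over %d pairs",
                rmsd, len(mapping))

    def _modes(model: CoarseModel, name: str):
        hessian = build_hessian(model, config.anm_cutoff)
        if name in config.subsystems:
            part = effective_hessian(hessian, config.subsystems[name])
            return subsystem_modes(part), part.subsystem
        return decompose(hessian), tuple(range(model.n_nodes))

    modes_a, sub_a = _modes(model_a, reference)
    modes_b, sub_b = _modes(model_b, other)

    # re-index the alignment into each (sub)system's node space
    pos_a = {node: i for i, node in enumerate(sub_a)}
    pos_b = {node: i for i, node in enumerate(sub_b)}
    pairs = tuple(
        (pos_a[a], pos_b[b]) for a, b in mapping.pairs
        if a in pos_a and b in pos_b
    )
    sub_mapping = AlignmentMap(pairs)

    n = min(config.n_modes, modes_a.n_modes, modes_b.n_modes)
    matrix = mode_correlation_matrix(modes_a, modes_b, sub_mapping, n)
    summary = family_overlap_summary(matrix, n)
    pd.DataFrame(
        matrix,
        index=[f"{reference}_mode{k + 1}" for k in range(n)],
        columns=[f"{other}_mode{k + 1}" for k in range(n)],
    ).to_csv(out / f"mode_overlap_{reference}_{other}.csv")
    outputs.append(str(out / f"mode_overlap_{reference}_{other}.csv"))

    _manifest(config, f"family_{reference}_{other}", outputs)
    return {
        "matrix": matrix,
        "summary_percent": summary,
        "superposition_rmsd": rmsd,
        "outputs": outputs,
    }
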