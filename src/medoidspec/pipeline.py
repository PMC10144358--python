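"""End-to-end configured runs: featurize -> cluster -> PCA -> spectra -> CT.

A run is fully determined by a single YAML config (strictly validated:
unknown keys are errors) and its mandatory seed; every output is written
to the configured directory together with a machine-readable report
(chosen K, medoid frames, populations, K-scan diagnostics, cost summary
and a checksummed file manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from medoidspec import cluster as _cluster
from medoidspec import features as _features
from medoidspec import pca as _pca
from medoidspec import spectra as _spectra
from medoidspec.ct import characterize_states
from medoidspec.states import read_omega_tsv, read_states_tsv
from medoidspec.trajectory import AtomSelection, read_pdb, read_xyz, uniform_subset

logger = logging.getLogger(__name__)

_TOP_KEYS = {
    "seed", "trajectory", "subset_count", "subset_stride", "skip",
    "features", "clustering", "spectrum", "omega", "output_dir",
}
_FEATURE_KEYS = {"recipe", "sel_a", "sel_b", "local_frame_atoms", "dihedrals",
                 "csm_selection", "csm_permutation"}
_CLUSTER_KEYS = {"k", "k_min", "k_max", "n_restarts"}
_SPECTRUM_KEYS = {"states", "sigma2", "grid"}


@dataclass
class RunConfig:
    """Validated run configuration; see the package README for the schema."""

    seed: int
    trajectory: str
    features: dict
    clustering: dict
    output_dir: str
    subset_count: int | None = None
    subset_stride: int | None = None
    skip: int = 0
    spectrum: dict | None = None
    omega: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        for section, allowed in (
            ("features", _FEATURE_KEYS),
            ("clustering", _CLUSTER_KEYS),
            ("spectrum", _SPECTRUM_KEYS),
        ):
            sec = raw.get(section)
            if sec is not None:
                bad = set(sec) - allowed
                if bad:
                    raise ValueError(f"unknown keys in {section!r}: {sorted(bad)}")
        base = base_dir or Path(".")

        def resolve(p):
            return str(p) if p is None or Path(p).is_absolute() else str(base / p)

        cfg = cls(
            seed=int(raw["seed"]),
            trajectory=resolve(raw["trajectory"]),
            features=dict(raw.get("features") or {}),
            clustering=dict(raw.get("clustering") or {}),
            output_dir=resolve(raw.get("output_dir", "medoidspec_out")),
            subset_count=raw.get("subset_count"),
            subset_stride=raw.get("subset_stride"),
            skip=int(raw.get("skip", 0)),
            spectrum=dict(raw["spectrum"]) if raw.get("spectrum") else None,
            omega=resolve(raw.get("omega")) if raw.get("omega") else None,
        )
        if cfg.spectrum and cfg.spectrum.get("states"):
            cfg.spectrum["states"] = resolve(cfg.spectrum["states"])
        if not Path(cfg.trajectory).exists():
            raise FileNotFoundError(f"trajectory not found: {cfg.trajectory}")
        return cfg


def cost_summary(n_frames: int, k: int) -> dict:
    """Computational-cost reduction from N frames to K representatives."""
    if k < 1 or n_frames < k:
        raise ValueError("need 1 <= K <= n_frames")
    factor = n_frames / k
    rounded = float(round(factor, -int(math.floor(math.log10(factor))))) if factor > 0 else 0.0
    return {"n_frames": n_frames, "k": k, "reduction_factor": factor,
            "reduction_factor_1sf": rounded}


def _featurize(traj, fcfg: dict) -> pd.DataFrame:
    recipe = fcfg.get("recipe", "plane-pair")
    if recipe == "plane-pair":
        feat = _features.PlanePairFeaturizer(
            sel_a=AtomSelection("A", tuple(fcfg["sel_a"])),
            sel_b=AtomSelection("B", tuple(fcfg["sel_b"])),
            local_frame_atoms=tuple(fcfg["local_frame_atoms"]),
        )
    elif recipe == "dihedral-csm":
        sel = fcfg.get("csm_selection")
        feat = _features.C2SymmetryFeaturizer(
            dihedrals=[tuple(d) for d in fcfg.get("dihedrals", [])],
            csm_selection=AtomSelection("csm", tuple(sel)) if sel else None,
            csm_permutation=fcfg.get("csm_permutation"),
        )
    else:
        raise ValueError(f"unknown feature recipe {recipe!r}")
    return feat.fit(traj).transform(traj)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "read_trajectory"
    try:
        reader = read_pdb if config.trajectory.endswith(".pdb") else read_xyz
        traj = reader(config.trajectory)
        logger.info("stage %s: %d frames in", stage, len(traj))
        if config.subset_count or config.subset_stride:
            traj = uniform_subset(
                traj, stride=config.subset_stride,
                target_count=config.subset_count, skip=config.skip,
            )
            logger.info("subset: %d frames out", len(traj))

        stage = "featurize"
        raw_features = _featurize(traj, config.features)
        numeric = raw_features.select_dtypes(include=[np.number])
        std, params = _features.standardize(numeric)
        features_path = out_dir / "features.tsv"
        raw_features.to_csv(features_path, sep="\t", index=False)

        stage = "cluster"
        ccfg = config.clustering
        n_restarts = int(ccfg.get("n_restarts", 8))
        if "k" in ccfg:
            chosen_k = int(ccfg["k"])
            scan = None
            sol = _cluster.pam(std, chosen_k, seed=config.seed, n_restarts=n_restarts)
        else:
            scan = _cluster.select_k(
                std, k_min=int(ccfg.get("k_min", 2)), k_max=int(ccfg.get("k_max", 10)),
                seed=config.seed, n_restarts=n_restarts,
            )
            chosen_k = scan.chosen_k
            sol = scan.solutions[chosen_k]
        clusters_path = out_dir / "clusters.tsv"
        is_medoid = np.zeros(len(std), dtype=bool)
        is_medoid[sol.medoid_indices] = True
        pd.DataFrame(
            {"frame_id": [fr.index for fr in traj], "label": sol.labels, "is_medoid": is_medoid}
        ).to_csv(clusters_path, sep="\t", index=False)

        stage = "pca"
        model = _pca.FeaturePCA().fit(std)
        scores = model.transform(std, n_components=min(2, std.shape[1]))
        scatter = _pca.cluster_scatter_export(scores, sol)
        pca_path = out_dir / "pca.tsv"
        scatter.to_csv(pca_path, sep="\t", index=False)

        report: dict = {
            "config": {"seed": config.seed, "trajectory": config.trajectory},
            "n_frames": len(traj),
            "chosen_k": chosen_k,
            "medoid_frame_ids": [int(traj[i].index) for i in sol.medoid_indices],
            "populations": [float(p) for p in sol.populations],
            "inertia": sol.inertia,
            "explained_fraction_2pc": float(model.explained_fraction_[: min(2, std.shape[1])].sum()),
            "dropped_columns": params.dropped,
            "cost": cost_summary(len(traj), chosen_k),
        }
        if scan is not None:
            report["k_scan"] = {
                "k_values": scan.k_values,
                "inertia": scan.inertias,
                "calinski_harabasz": [
                    (None if not np.isfinite(c) else float(c)) for c in scan.ch_scores
                ],
                "elbow_k": scan.elbow_k,
                "rule": scan.rule,
            }

        manifest = {p.name: _sha256(p) for p in (features_path, clusters_path, pca_path)}

        if config.spectrum and config.spectrum.get("states"):
            stage = "spectrum"
            states = read_states_tsv(config.spectrum["states"])
            sigma2 = float(config.spectrum.get("sigma2", _spectra.DEFAULT_SIGMA2))
            gspec = config.spectrum.get("grid", list(_spectra.DEFAULT_GRID))
            grid = _spectra.make_grid(*gspec)
            full = _spectra.ensemble_spectrum(states, grid=grid, sigma2=sigma2)
            medoid_fids = report["medoid_frame_ids"]
            med_states = states.restrict(medoid_fids)
            pops = {fid: float(p) for fid, p in zip(medoid_fids, sol.populations)}
            med = _spectra.medoid_spectrum(med_states, pops, grid=grid, sigma2=sigma2)
            dev = _spectra.spectrum_integral_deviation(med, full)
            p_full = out_dir / "spectrum_full.tsv"
            p_med = out_dir / "spectrum_medoid.tsv"
            _spectra.write_spectrum_tsv(full, p_full)
            _spectra.write_spectrum_tsv(med, p_med)
            manifest[p_full.name] = _sha256(p_full)
            manifest[p_med.name] = _sha256(p_med)
            report["spectrum"] = {
                "sigma2": sigma2,
                "integrated_abs_deviation": dev,
                "full_peak_ev": full.argmax_energy(),
                "medoid_peak_ev": med.argmax_energy(),
            }

        if config.omega:
            stage = "ct_descriptors"
            records = read_omega_tsv(config.omega)
            ct_report = characterize_states(records)
            p_ct = out_dir / "ct_report.tsv"
            ct_report.to_csv(p_ct, sep="\t", index=False)
            manifest[p_ct.name] = _sha256(p_ct)
            report["ct_states"] = len(ct_report)

        report["manifest"] = manifest
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
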