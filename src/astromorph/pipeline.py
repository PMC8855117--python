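"""End-to-end orchestration: data -> features -> morphotypes -> inference.

A single :class:`PipelineConfig` drives either the synthetic demonstration
(default) or an analysis of user-supplied SWC reconstructions plus a genotype
table.  Every stage writes its artifacts to the output directory and the whole
run is summarised in a deterministic ``report.json`` (fixed seed + config ->
byte-identical output).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import morpho_classify as mc
from . import perm_stats as ps
from . import popgen_assoc as pg
from . import synthetic_data as sd
from .morphology_io import correct_z_shrinkage, read_swc
from .morphometry import features_table

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("astromorph")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with the study's defaults.

    When ``swc_dir`` is unset the pipeline generates synthetic inputs
    (``n_classes`` morphotype classes, four-species genotypes).
    """

    # inputs (real-data mode)
    swc_dir: str | None = None
    metadata: str | None = None
    genotypes: str | None = None
    distances: str | None = None
    # synthetic mode
    n_classes: int = 3
    n_per_class: int = 40
    genotype_delta_bp: float = 4.0
    genotype_sd_bp: float = 2.0
    # analysis parameters
    z_factor: float = 1.75
    mmi_threshold: float = 0.55
    k_range: tuple[int, int] = (2, 6)
    k_override: int | None = None
    n_perm: int = 9999
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "astromorph_out"
    run_genetics: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mmi_threshold <= 0:
            raise ValueError("mmi_threshold must be positive")
        if self.z_factor <= 0:
            raise ValueError("z_factor must be positive")
        self.k_range = tuple(self.k_range)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1,
                               default=_json_default) + "\n")


def _load_cells(cfg: PipelineConfig):
    swc_dir = Path(cfg.swc_dir)
    meta = pd.read_csv(cfg.metadata) if cfg.metadata else None
    cells = []
    for path in sorted(swc_dir.glob("*.swc")):
        cell = read_swc(path)
        if meta is not None:
            row = meta[meta["cell_id"] == cell.cell_id]
            if not row.empty:
                cell.species = str(row.iloc[0].get("species", ""))
                cell.individual = str(row.iloc[0].get("individual", ""))
        cells.append(correct_z_shrinkage(cell, cfg.z_factor))
    if not cells:
        raise PipelineError(f"stage morphology: no SWC files under {swc_dir}")
    return cells, meta


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.run_genetics and config.swc_dir and not config.genotypes:
        raise PipelineError("stage popgen: config field 'genotypes' is "
                            "required when genetics is enabled")
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_perm": config.n_perm,
        },
        "config": config.to_dict(),
    }
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(
                 ["cells", "genotypes", "permanova", "permdisp", "pairwise",
                  "popgen", "association"], ss.spawn(7))}

    # --- stage 1: morphology ------------------------------------------------
    try:
        if config.swc_dir:
            cells, meta = _load_cells(config)
            true_labels = None
        else:
            classes = (sd.DEFAULT_THREE_CLASSES if config.n_classes == 3
                       else sd.DEFAULT_FOUR_CLASSES if config.n_classes == 4
                       else None)
            if classes is None:
                raise PipelineError("stage morphology: n_classes must be 3 or 4")
            cells, true_labels, meta = sd.generate_population(
                classes, config.n_per_class, seed=seeds["cells"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage morphology: {exc}") from exc
    report["cells"] = {"n": len(cells)}
    log.info("stage morphology: %d cells", len(cells))

    # --- stage 2: features --------------------------------------------------
    try:
        feats = features_table(cells)
        meta_idx = meta.set_index("cell_id") if meta is not None else None
        feats_out = feats.copy()
        if meta_idx is not None:
            for col in ("species", "individual"):
                if col in meta_idx.columns:
                    feats_out[col] = meta_idx[col].reindex(feats.index)
        feats_out.to_csv(out / "features.csv")
    except Exception as exc:
        raise PipelineError(f"stage features: {exc}") from exc
    report["features"] = {"n_cells": len(feats), "n_features": feats.shape[1]}

    # --- stage 3: morphotype classification ---------------------------------
    try:
        selected = mc.select_features(feats, threshold=config.mmi_threshold)
        transformed = mc.shrink_log_transform(feats[selected])
        selected = list(transformed.columns)
        result = mc.ward_cluster(transformed, k_range=config.k_range,
                                 k=config.k_override)
        disc = mc.discriminant_validation(transformed[selected], result.labels,
                                          alpha=config.alpha)
        reps = mc.representative_cell(transformed, result.labels)
        result.representative = reps
        logc = np.log10(feats["complexity"].to_numpy(float))
        n_peaks, peak_locs = mc.kernel_density_peaks(logc)
    except Exception as exc:
        raise PipelineError(f"stage classify: {exc}") from exc

    pd.DataFrame({"cell_id": result.labels.index,
                  "morphotype": result.labels.to_numpy()}
                 ).to_csv(out / "clusters.csv", index=False)
    _write_json({"merges": result.linkage.tolist(),
                 "k": result.k, "k_scores": {str(k): v for k, v in
                                             result.k_scores.items()}},
                out / "linkage.json")
    _write_json({
        "entered_features": disc.features,
        "eigenvalues": disc.eigenvalues,
        "pct_variance": disc.pct_variance,
        "wilks_lambda": disc.wilks_lambda,
        "wilks_p": disc.wilks_p,
        "structure_matrix": {c: disc.structure_matrix[c].to_dict()
                             for c in disc.structure_matrix.columns},
        "confusion": disc.confusion.to_numpy(),
        "accuracy_pct": disc.accuracy_pct,
    }, out / "discriminant.json")
    _write_json({"n_peaks": n_peaks, "locations_log10": peak_locs},
                out / "density_peaks.json")

    report["classify"] = {
        "selected_features": selected,
        "k": result.k,
        "cluster_sizes": {str(k): int(v) for k, v in
                          result.labels.value_counts().sort_index().items()},
        "representative_cells": {str(k): v for k, v in reps.items()},
        "discriminant_accuracy_pct": disc.accuracy_pct,
        "wilks_lambda_first_test": float(disc.wilks_lambda[0]),
        "pct_variance_function1": float(disc.pct_variance[0]),
        "density_peaks": n_peaks,
    }
    if true_labels is not None:
        from sklearn.metrics import adjusted_rand_score
        report["classify"]["ari_vs_generator"] = float(
            adjusted_rand_score(true_labels, result.labels.to_numpy()))
    log.info("stage classify: k=%d, accuracy=%.1f%%", result.k,
             disc.accuracy_pct)

    # --- stage 4: permutation inference on morphometry ----------------------
    try:
        dm = ps.assemble_distance_matrix(feats[selected])
        species = (meta.set_index("cell_id")["species"]
                   .reindex(feats.index).fillna("synthetic"))
        design = pd.DataFrame({"species": species.to_numpy(),
                               "type": result.labels.to_numpy()},
                              index=feats.index)
        factors = [c for c in ("species", "type") if design[c].nunique() >= 2]
        perm_results = ps.permanova(dm, design, factors=factors,
                                    n_perm=config.n_perm,
                                    seed=seeds["permanova"])
        cell_groups = design[factors].astype(str).agg("|".join, axis=1)
        disp, disp_pairs = ps.permdisp(dm, cell_groups.to_numpy(),
                                       n_perm=config.n_perm,
                                       seed=seeds["permdisp"])
        pair_t = ps.pairwise_pseudo_t(dm, result.labels.to_numpy(),
                                      n_perm=config.n_perm,
                                      seed=seeds["pairwise"])
        glm = ps.univariate_glm_posthoc(
            np.log10(feats["complexity"].to_numpy(float)),
            result.labels.to_numpy())
    except Exception as exc:
        raise PipelineError(f"stage perm_stats: {exc}") from exc

    perm_rows = [{"term": r.term, "statistic": r.statistic_name,
                  "value": r.observed, "n_perm": r.n_perm, "seed": r.seed,
                  "p": r.p} for r in perm_results]
    perm_rows.append({"term": "dispersion", "statistic": disp.statistic_name,
                      "value": disp.observed, "n_perm": disp.n_perm,
                      "seed": disp.seed, "p": disp.p})
    pd.DataFrame(perm_rows).to_csv(out / "permanova.csv", index=False)
    pair_t.to_csv(out / "pairwise_pseudo_t.csv", index=False)
    disp_pairs.to_csv(out / "permdisp_pairwise.csv", index=False)
    report["perm_stats"] = {
        "permanova": {r.term: {"pseudo_F": r.observed, "p": r.p,
                               "n_perm": r.n_perm, "seed": r.seed}
                      for r in perm_results},
        "permdisp": {"F": disp.observed, "p": disp.p, "n_perm": disp.n_perm,
                     "seed": disp.seed},
        "glm_complexity": {"F": glm.F, "p": glm.p},
    }

    # --- stage 5 + 6: genetics and association ------------------------------
    if config.run_genetics:
        try:
            if config.genotypes:
                geno = pg.load_genotypes(config.genotypes)
            elif config.swc_dir:
                raise PipelineError("stage popgen: config field 'genotypes' is "
                                    "required when genetics is enabled")
            else:
                spec = sd.default_genotype_spec(config.genotype_delta_bp,
                                                config.genotype_sd_bp)
                geno = sd.generate_genotypes(spec, seed=seeds["genotypes"])
                geno.to_csv(out / "genotypes.csv", index=False)
            if config.distances:
                dmap_df = pd.read_csv(config.distances)
                dmap = dict(zip(dmap_df["species"], dmap_df["km"].astype(float)))
            else:
                dmap = pg.DEFAULT_MIGRATORY_DISTANCES_KM

            summary = pg.allele_summary(geno)
            hwe = pg.hwe_test(geno, n_perm=min(config.n_perm, 999),
                              seed=seeds["popgen"])
            diff = pg.fst_rst(geno, n_perm=min(config.n_perm, 999),
                              seed=seeds["popgen"])
            assoc = pg.distance_association(geno, dmap, n_perm=config.n_perm,
                                            seed=seeds["association"])
            comp, comp_pairs = pg.allele_size_group_comparison(
                geno, n_perm=config.n_perm, seed=seeds["association"])
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage popgen: {exc}") from exc

        summary.to_csv(out / "genetics_diversity.csv")
        diff.fst.to_csv(out / "fst.csv")
        diff.rst.to_csv(out / "rst.csv")
        comp_pairs.to_csv(out / "allele_size_pairwise.csv", index=False)
        report["genetics"] = {
            "diversity": {sp: {k: (int(v) if isinstance(v, (int, np.integer))
                                   else float(v))
                               for k, v in row.items()}
                          for sp, row in summary.iterrows()},
            "hwe_p": {k: float(v) for k, v in hwe.items()},
            "fst_mean_offdiag": float(
                diff.fst.to_numpy()[~np.eye(len(diff.species), dtype=bool)]
                .mean()),
        }
        report["association"] = {
            "spearman_rho": assoc.rho, "p": assoc.p,
            "regression_R": assoc.regression_r,
            "n": assoc.n, "n_perm": assoc.n_perm, "seed": assoc.seed,
            "allele_size_permanova": {"pseudo_F": comp.observed, "p": comp.p,
                                      "n_perm": comp.n_perm, "seed": comp.seed},
        }
        log.info("stage association: rho=%.3f (p=%.4g)", assoc.rho, assoc.p)

    _write_json(report, out / "report.json")
    return report
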