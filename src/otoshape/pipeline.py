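"""End-to-end analysis: signatures -> wavelet features -> morphospace ->
population tests -> classification -> morphotypes.

One master seed fans out to per-stage seeds through a fixed counter scheme
(SeedSequence(master, spawn_key=(stage,)) with stage 0 = simulation,
1 = PERMANOVA, 2 = classification, 3 = morphotypes), so no stage touches
global random state and a re-run with the same seed regenerates every output
identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, confusion_metrics, loocv_classify
from .contour import canonical_orientation, otolith_length, resample_equidistant, signature
from .io import config_hash, load_sample, write_matrix_csv, write_report_json
from .morphospace import allometric_residuals, pca_covariance, size_correlation
from .morphotypes import (
    cut_tree,
    morphotype_composition,
    morphotype_separation_test,
    silhouette_profile,
    ward_cluster,
)
from .permanova import manhattan_distances, permanova_global, permanova_pairwise
from .wavelet import atrous_decompose, select_scale

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "signatures_from_manifest",
           "features_from_signatures", "stage_seed"]

_STAGES = {"simulate": 0, "permanova": 1, "classify": 2, "morphotypes": 3}


class PipelineError(RuntimeError):
    """Stage failure, tagged with the stage name (and sample ids if known)."""


@dataclass
class RunConfig:
    """Every stage's tunables plus the master seed."""

    n_points: int = 512
    wavelet_levels: int = 9
    wavelet_scale: int = 4
    adjust: str = "all"  # 'all' | 'significant' retained components
    alpha: float = 0.05  # screen level when adjust='significant'
    min_retained: int = 2
    n_perm: int = 999
    k_morphotypes: int = 5
    assume_left: bool = False
    # pipeline default is desk-scale: small grid, 3 inner folds, 3 repeats
    # (raise repeats and widen the grid for publication-scale replication)
    classifier: ClassifierConfig = field(
        default_factory=lambda: ClassifierConfig(
            hidden_units_grid=(5, 13), inner_folds=3, repeats=3
        )
    )
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifier"]["hidden_units_grid"] = list(d["classifier"]["hidden_units_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "classifier" in d and isinstance(d["classifier"], dict):
            c = dict(d["classifier"])
            if "hidden_units_grid" in c:
                c["hidden_units_grid"] = tuple(c["hidden_units_grid"])
            d["classifier"] = ClassifierConfig(**c)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed."""
    key = _STAGES[stage]
    return int(np.random.SeedSequence(master, spawn_key=(key,)).generate_state(1)[0] % 2**31)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def signatures_from_manifest(manifest: pd.DataFrame, config: RunConfig) -> np.ndarray:
    """Manifest rows -> (N, n_points) matrix of shape signatures."""
    rows = []
    for _, rec in manifest.iterrows():
        try:
            side = rec.get("side") if isinstance(rec.get("side"), str) else None
            c = load_sample(rec["path"], side=side)
            c = canonical_orientation(c, assume_left=config.assume_left)
            c = resample_equidistant(c, n=config.n_points)
            rows.append(signature(c).distances)
        except Exception as exc:
            raise PipelineError(
                f"stage 'signature' failed for sample {rec['sample_id']!r}: {exc}"
            ) from exc
    return np.vstack(rows)


def features_from_signatures(signatures: np.ndarray, config: RunConfig) -> np.ndarray:
    """Per-row à trous decomposition, keeping the configured detail scale."""
    return np.vstack([
        select_scale(atrous_decompose(s, levels=config.wavelet_levels), config.wavelet_scale).values
        for s in signatures
    ])


def run_pipeline(manifest: pd.DataFrame, config: RunConfig, outdir) -> dict:
    """Run every stage on a loaded manifest and write all outputs to ``outdir``.

    Returns the run report (also written as report.json): seeds, parameters,
    retained components, test statistics, classification metrics and
    morphotype composition.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config.to_dict())
    ids = manifest["sample_id"].tolist()
    pops = manifest["population"].to_numpy()
    if "OL_mm" in manifest.columns and manifest["OL_mm"].notna().all():
        sizes = manifest["OL_mm"].to_numpy(dtype=float)
        size_source = "manifest OL_mm"
    else:
        sizes = None
        size_source = "measured from contours"

    sigs = signatures_from_manifest(manifest, config)
    write_matrix_csv(outdir / "signatures.csv", ids, sigs,
                     [f"d{i}" for i in range(config.n_points)], __version__, cfg_hash)

    feats = _stage("wavelet", features_from_signatures, sigs, config)
    write_matrix_csv(outdir / "features.csv", ids, feats,
                     [f"w{i}" for i in range(config.n_points)], __version__, cfg_hash)

    if sizes is None:
        def _measure_sizes():
            out = []
            for _, rec in manifest.iterrows():
                side = rec.get("side") if isinstance(rec.get("side"), str) else None
                c = canonical_orientation(load_sample(rec["path"], side=side),
                                          assume_left=True)
                out.append(otolith_length(c))
            return np.asarray(out)
        sizes = _stage("otolith_length", _measure_sizes)

    model = _stage("pca", pca_covariance, feats)
    retained = model.retained
    if retained < config.min_retained:
        raise PipelineError(
            f"stage 'pca' failed: broken-stick retained only {retained} component(s); "
            f"at least {config.min_retained} are needed — check that the feature "
            "matrix has real structure or lower min_retained"
        )
    scores = model.scores[:, :retained]
    r, p = _stage("size_correlation", size_correlation, scores, sizes)
    adj = _stage("allometry", allometric_residuals, scores, sizes, pops)
    if config.adjust == "significant":
        keep_trend = p >= config.alpha  # components without a size signal keep raw scores
        adjusted = np.where(keep_trend[None, :], scores, adj.scores)
    elif config.adjust == "all":
        adjusted = adj.scores
    else:
        raise PipelineError(f"stage 'allometry' failed: unknown adjust={config.adjust!r}")
    write_matrix_csv(outdir / "scores.csv", ids, adjusted,
                     [f"PC{i+1}" for i in range(retained)], __version__, cfg_hash)

    D = _stage("permanova", manhattan_distances, adjusted)
    global_res = _stage("permanova", permanova_global, D, pops,
                        n_perm=config.n_perm, seed=stage_seed(config.seed, "permanova"))
    pairwise = _stage("permanova", permanova_pairwise, D, pops,
                      n_perm=config.n_perm, seed=stage_seed(config.seed, "permanova"))
    pairwise.to_csv(outdir / "permanova_pairwise.csv", index=False)

    clf_cfg = dataclasses.replace(config.classifier, seed=stage_seed(config.seed, "classify"))
    loocv = _stage("classify", loocv_classify, adjusted, pops, clf_cfg)
    loocv.matrix.to_frame().to_csv(outdir / "confusion.csv")
    mean_metrics = confusion_metrics(loocv.matrix)

    dend = _stage("morphotypes", ward_cluster, adjusted)
    assignments = _stage("morphotypes", cut_tree, dend, config.k_morphotypes)
    table = _stage("morphotypes", morphotype_composition, assignments, pops)
    table.proportions.to_csv(outdir / "morphotype_proportions.csv")
    pd.DataFrame({"sample_id": ids, "morphotype": assignments}).to_csv(
        outdir / "morphotype_assignments.csv", index=False)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        sep = _stage("morphotypes", morphotype_separation_test, adjusted, assignments,
                     config.n_perm, stage_seed(config.seed, "morphotypes"))
    silhouettes = _stage("morphotypes", silhouette_profile, adjusted)

    report = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "n_samples": len(ids),
        "size_source": size_source,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "pca": {
            "retained": retained,
            "variance_fraction_retained": model.variance_fraction[:retained].tolist(),
            "total_variance": float(model.eigenvalues.sum()),
        },
        "size_correlation": {"r": r.tolist(), "p": p.tolist(),
                             "note": "no multiple-testing correction applied to this screen"},
        "allometric_slopes": adj.slopes.tolist(),
        "permanova": {
            "pseudo_F": global_res.pseudo_F,
            "p_value": global_res.p_value,
            "df_among": global_res.df_among,
            "df_within": global_res.df_within,
            "n_permutations": global_res.n_permutations,
        },
        "classification": {
            "accuracy": mean_metrics.accuracy,
            "kappa": mean_metrics.kappa,
            "per_class_accuracy": mean_metrics.per_class_accuracy,
            "repeats": loocv.repeats,
            "chosen_hidden_units": loocv.chosen_hidden_units,
        },
        "morphotypes": {
            "k": config.k_morphotypes,
            "separation_pseudo_F": sep.pseudo_F,
            "separation_p": sep.p_value,
            "separation_note": sep.note,
            "silhouette_by_k": silhouettes,
            "proportions": {str(c): table.proportions[c].to_dict()
                            for c in table.proportions.columns},
        },
    }
    write_report_json(report, outdir / "report.json")
    config.save(outdir / "config.yaml")
    return report
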