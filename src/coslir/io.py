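"""Reading expression matrices, writing edge tables, and the pipeline."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .bootstrap import bootstrap_grn
from .evaluate import rescale_matrix
from .moments import StageSample, estimate_moments
from .selection import select_clipping_threshold, select_hyperparameters
from .solver import SolverConfig, admm_fit

logger = logging.getLogger("coslir")

__all__ = ["RunConfig", "load_expression", "write_network", "read_network",
           "write_moments", "read_moments", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, echoed into the run manifest."""

    expression_path: str = ""
    metadata_path: str = ""
    orientation: str = "genes_by_cells"
    stage_order: list = field(default_factory=list)
    out_dir: str = "coslir_out"
    seed: int = 0
    lam: float = 1e-6
    eta: float = 5.0
    alpha: float = 0.01
    log_transform: bool = False
    lam_grid: list = field(default_factory=lambda: [1e-6])
    eta_grid: list = field(default_factory=lambda: [5.0])
    eps_grid: list = field(default_factory=lambda: list(
        np.concatenate([[0.0], np.geomspace(1e-3, 0.3, 13)])))
    select_hyper: bool = False
    n_reps: int = 50
    conf_threshold: float = 0.9
    max_iter: int = 5000
    overwrite: bool = False
    log_level: str = "INFO"


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_expression(path, metadata_path, orientation: str = "genes_by_cells",
                    fmt: str | None = None):
    """Load a genes x cells expression matrix plus stage metadata.

    Parameters
    ----------
    path : str or Path
        CSV/TSV with row and column labels, or Matrix Market ``.mtx``
        with ``<stem>_genes.txt`` and ``<stem>_cells.txt`` sidecars.
    metadata_path : str or Path
        Two-column table (cell_id, stage); header optional but the first
        column must be the cell identifier.
    orientation : {"genes_by_cells", "cells_by_genes"}
        Orientation of the main matrix.

    Returns
    -------
    dict mapping stage label -> StageSample, with a common gene order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    fmt = fmt or ("mtx" if path.suffix.lower() == ".mtx" else "delim")
    if fmt == "mtx":
        mat = spio.mmread(path)
        mat = np.asarray(mat.todense() if sparse.issparse(mat) else mat,
                         dtype=float)
        genes_file = path.with_name(path.stem + "_genes.txt")
        cells_file = path.with_name(path.stem + "_cells.txt")
        row_names = genes_file.read_text().split()
        col_names = cells_file.read_text().split()
        df = pd.DataFrame(mat, index=row_names, columns=col_names)
    else:
        df = _read_table(path)
    if orientation == "cells_by_genes":
        df = df.T
    # now rows = genes, columns = cells
    meta = pd.read_csv(metadata_path,
                       sep=None, engine="python")
    if meta.shape[1] < 2:
        raise ValueError("metadata needs (cell_id, stage) columns")
    meta = meta.iloc[:, :2]
    meta.columns = ["cell_id", "stage"]
    meta["cell_id"] = meta["cell_id"].astype(str)
    if meta["cell_id"].duplicated().any():
        dupes = meta.loc[meta["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell ids in metadata: {dupes[:5]}")
    cells = [str(c) for c in df.columns]
    known = set(meta["cell_id"])
    missing = [c for c in cells if c not in known]
    if missing:
        # a cells-by-genes file loaded as genes-by-cells puts gene names in
        # the columns; all of them will be absent from the metadata
        if len(missing) == len(cells):
            raise ValueError(
                "none of the matrix columns appear in the metadata; "
                "check the orientation flag (no silent transpose is done)"
            )
        raise ValueError(f"cells without stage label: {missing[:5]}")
    stage_of = dict(zip(meta["cell_id"], meta["stage"]))
    gene_names = [str(g) for g in df.index]
    values = df.to_numpy(dtype=float)
    stages: dict[str, list[int]] = {}
    for j, c in enumerate(cells):
        stages.setdefault(str(stage_of[c]), []).append(j)
    return {
        lab: StageSample(values=values[:, idx], gene_names=gene_names,
                         stage_label=lab)
        for lab, idx in stages.items()
    }


def write_moments(moments, path):
    """Store a stage's moments as a self-describing .npz archive."""
    np.savez(
        path,
        mean=moments.mean,
        covariance=moments.covariance,
        covariance_raw=moments.covariance_raw,
        alpha=np.array([moments.alpha]),
        n_cells=np.array([moments.n_cells]),
    )


def read_moments(path):
    from .moments import MomentSummary
    with np.load(path) as z:
        return MomentSummary(
            mean=z["mean"], covariance_raw=z["covariance_raw"],
            covariance=z["covariance"], alpha=float(z["alpha"][0]),
            n_cells=int(z["n_cells"][0]),
        )


def write_network(final, gene_names, path, confidence=None, rescaled=None,
                  overwrite: bool = False, sif: bool = False):
    """Write the nonzero entries of ``final`` as a TSV edge table.

    Columns: regulator, target, weight, sign, confidence, rescaled.  One
    row per nonzero entry, sorted by |rescaled| (falling back to
    |weight|) descending, then lexicographically.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True)")
    final = np.asarray(final, dtype=float)
    p = final.shape[0]
    if len(gene_names) != p:
        raise ValueError("gene_names length does not match matrix")
    rows, cols = np.nonzero(final)
    recs = []
    for i, j in zip(rows, cols):
        w = final[i, j]
        recs.append({
            "regulator": gene_names[j],
            "target": gene_names[i],
            "weight": w,
            "sign": int(np.sign(w)),
            "confidence": float(confidence[i, j])
            if confidence is not None else np.nan,
            "rescaled": float(rescaled[i, j])
            if rescaled is not None else np.nan,
        })
    df = pd.DataFrame(recs, columns=["regulator", "target", "weight",
                                     "sign", "confidence", "rescaled"])
    if len(df):
        key = df["rescaled"].abs()
        if key.isna().all():
            key = df["weight"].abs()
        df = df.assign(_k=key).sort_values(
            ["_k", "regulator", "target"], ascending=[False, True, True]
        ).drop(columns="_k")
    df.to_csv(path, sep="\t", index=False)
    if sif:
        sif_path = path.with_suffix(".sif")
        with open(sif_path, "w") as fh:
            for r in df.itertuples():
                rel = "activates" if r.sign > 0 else "represses"
                fh.write(f"{r.regulator}\t{rel}\t{r.target}\n")
    return df


def read_network(path, gene_names):
    """Rebuild the dense matrix from an edge TSV written by write_network."""
    df = pd.read_csv(path, sep="\t")
    idx = {g: i for i, g in enumerate(gene_names)}
    p = len(gene_names)
    A = np.zeros((p, p))
    for r in df.itertuples():
        A[idx[str(r.target)], idx[str(r.regulator)]] = r.weight
    return A


def _anisotropy_warning(moments, stage):
    eig = np.linalg.eigvalsh(moments.covariance)
    if eig.min() > 0 and eig.max() / eig.min() > 1e6:
        logger.warning(
            "stage %s covariance is extremely anisotropic "
            "(condition %.1e); consider whether the stage mixes "
            "heterogeneous subpopulations", stage, eig.max() / eig.min())


def run_pipeline(cfg: RunConfig, samples=None):
    """Run moments -> selection -> bootstrap for each consecutive stage pair.

    ``samples`` may be given directly (dict stage -> StageSample) to
    bypass file loading.  Returns a dict keyed by ``"t->t+1"`` pair label
    with the bootstrap result, the chosen thresholds and output paths.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if samples is None:
        samples = load_expression(cfg.expression_path, cfg.metadata_path,
                                  cfg.orientation)
    order = cfg.stage_order or sorted(samples)
    missing = [s for s in order if s not in samples]
    if missing:
        raise ValueError(f"stage(s) {missing} not present in the data")
    if len(order) < 2:
        raise ValueError("need at least 2 stages")
    results = {}
    manifest = {"config": {k: (list(v) if isinstance(v, (list, tuple))
                               else v)
                           for k, v in asdict(cfg).items()},
                "pairs": {}}
    for a, b in zip(order[:-1], order[1:]):
        pair = f"{a}->{b}"
        s_t, s_t1 = samples[a], samples[b]
        if s_t.n_cells < 2 or s_t1.n_cells < 2:
            logger.warning("skipping pair %s: a stage has < 2 cells", pair)
            manifest["pairs"][pair] = {"skipped": "stage with < 2 cells"}
            continue
        if cfg.log_transform:
            s_t = StageSample(np.log1p(s_t.values), s_t.gene_names, a)
            s_t1 = StageSample(np.log1p(s_t1.values), s_t1.gene_names, b)
        m_t = estimate_moments(s_t, alpha=cfg.alpha)
        m_t1 = estimate_moments(s_t1, alpha=cfg.alpha)
        _anisotropy_warning(m_t, a)
        scfg = SolverConfig(lam=cfg.lam, eta=cfg.eta, max_iter=cfg.max_iter)
        if cfg.select_hyper:
            lam, eta, table = select_hyperparameters(
                m_t, m_t1, cfg.lam_grid, cfg.eta_grid, cfg=scfg)
            table.to_csv(out_dir / f"{pair}_hyper.tsv", sep="\t", index=False)
        else:
            lam, eta = cfg.lam, cfg.eta
        scfg = SolverConfig(lam=lam, eta=eta, max_iter=cfg.max_iter)
        full_fit = admm_fit(m_t, m_t1, scfg, gene_names=s_t.gene_names)
        choice = select_clipping_threshold(
            full_fit.A, m_t, m_t1, eta=eta, eps_grid=cfg.eps_grid)
        logger.info("pair %s: lam=%g eta=%g eps=%g (score %.3f, iters %d, "
                    "residuals %s)", pair, lam, eta, choice.epsilon,
                    choice.score, full_fit.n_iter,
                    full_fit.diagnostics["primal_residuals"])
        boot = bootstrap_grn(
            s_t, s_t1, scfg, epsilon=choice.epsilon, n_reps=cfg.n_reps,
            conf_threshold=cfg.conf_threshold, base_seed=cfg.seed,
            alpha=cfg.alpha)
        resc = rescale_matrix(boot.final, m_t.mean, m_t1.mean)
        edge_path = out_dir / f"{pair.replace('->', '_to_')}_edges.tsv"
        write_network(boot.final, s_t.gene_names, edge_path,
                      confidence=boot.confidence, rescaled=resc.values,
                      overwrite=cfg.overwrite, sif=True)
        results[pair] = {
            "bootstrap": boot,
            "full_fit": full_fit,
            "epsilon": choice.epsilon,
            "lam": lam,
            "eta": eta,
            "edges_path": str(edge_path),
            "rescaled": resc,
        }
        manifest["pairs"][pair] = {
            "lam": lam, "eta": eta, "epsilon": choice.epsilon,
            "n_replicates": boot.n_replicates,
            "conf_threshold": cfg.conf_threshold,
            "base_seed": cfg.seed,
            "edges": str(edge_path),
            "solver_iterations": full_fit.n_iter,
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
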