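"""File I/O, model/grid configuration, and evaluation studies on simulated
fields: per-realisation extrapolation errors, the random-design baseline, and
criterion scatter studies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .ek_criteria import mek
from .fisher_information import criterion_pair, j_alpha
from .design_search import perturbed_lh_sample
from .gp_core import (
    CandidateSet,
    CovarianceKernel,
    Design,
    GPModel,
    kriging_weights_many,
    simulate_field,
)

logger = logging.getLogger("ekdesign")


# ---------------------------------------------------------------------------
# configuration and file formats
# ---------------------------------------------------------------------------

def kernel_from_config(cfg: dict) -> CovarianceKernel:
    """Kernel from a config mapping: family, parameters, optional anisotropy
    {angle, ratio}, optional est_params list."""
    family = cfg["family"]
    params = {
        k: float(v)
        for k, v in cfg.items()
        if k in ("nu", "phi", "kappa")
    }
    aniso = None
    if "anisotropy" in cfg and cfg["anisotropy"] is not None:
        a = cfg["anisotropy"]
        aniso = (float(a["angle"]), float(a["ratio"]))
    est = tuple(cfg["est_params"]) if "est_params" in cfg else None
    return CovarianceKernel(
        family=family, params=params, anisotropy=aniso, est_params=est
    )


def model_from_config(cfg: dict) -> GPModel:
    """GPModel from a mapping {kernel: {...}, sigma2, trend}."""
    return GPModel(
        kernel=kernel_from_config(cfg["kernel"]),
        sigma2=float(cfg.get("sigma2", 1.0)),
        trend=cfg.get("trend", "constant"),
    )


def load_model(path: str) -> GPModel:
    with open(path) as fh:
        return model_from_config(yaml.safe_load(fh))


def load_candidate_set(path: str) -> CandidateSet:
    """Candidate set from a JSON grid spec {type: grid, m, lo, hi} or a CSV
    with columns x,y[,mask]."""
    if path.endswith(".json"):
        with open(path) as fh:
            spec = json.load(fh)
        if spec.get("type") != "grid":
            raise ValueError("JSON candidate spec must have type='grid'")
        return CandidateSet.grid(
            int(spec["m"]), float(spec.get("lo", 0.0)), float(spec.get("hi", 1.0))
        )
    df = pd.read_csv(path)
    pts = df[["x", "y"]].to_numpy(dtype=float)
    if "mask" in df.columns:
        pts = pts[df["mask"].to_numpy(dtype=bool)]
    return CandidateSet(points=pts)


def load_design(path: str) -> Design:
    df = pd.read_csv(path)
    return Design(df[["x", "y"]].to_numpy(dtype=float))


def save_design(design: Design, path: str) -> None:
    pd.DataFrame(design.sites, columns=["x", "y"]).to_csv(path, index=False)


def save_front_csv(front, path: str) -> None:
    front.to_table().to_csv(path, index=False)


def result_json(result, extra: dict | None = None) -> str:
    """Self-describing JSON for a SearchResult (config echo, seed, counters)."""
    import ekdesign

    payload = {
        "version": ekdesign.__version__,
        "seed": result.seed,
        "config": result.config,
        "counters": result.counters,
        "best_value": result.best_value,
        "best_design": result.best_design.sites.tolist(),
    }
    if extra:
        payload.update(extra)
    return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# evaluation studies
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Extrapolation-error summary over simulated field realisations."""

    per_realization: pd.DataFrame   # columns: realization, design, E_j
    summaries: pd.DataFrame         # per design: median E_j, max empirical MSE
    n_real: int
    seed: int


def field_eval(
    designs: dict[str, Design] | list[Design],
    model: GPModel,
    cands: CandidateSet,
    n_real: int,
    seed: int,
) -> EvaluationReport:
    """Simulate ``n_real`` field realisations over the candidate grid and,
    for each design, krige all grid values from the design-site values with
    the generating parameters.  Reports E_j = max squared extrapolation error
    per realisation and the empirical maximum mean-square error per design.
    """
    if isinstance(designs, list):
        designs = {f"design_{i}": d for i, d in enumerate(designs)}
    fields = simulate_field(cands, model, n_real, seed)      # (M, Q)
    rows = []
    summaries = []
    for name, d in designs.items():
        di = cands.index_of(d.sites)
        W, _ = kriging_weights_many(cands.points, d, model)  # (Q, n)
        preds = fields[:, di] @ W.T                          # (M, Q)
        sq = (preds - fields) ** 2
        E = sq.max(axis=1)
        rows.append(
            pd.DataFrame({"realization": np.arange(n_real), "design": name, "E_j": E})
        )
        summaries.append(
            {
                "design": name,
                "median_E": float(np.median(E)),
                "max_empirical_mse": float(sq.mean(axis=0).max()),
            }
        )
    return EvaluationReport(
        per_realization=pd.concat(rows, ignore_index=True),
        summaries=pd.DataFrame(summaries),
        n_real=n_real,
        seed=seed,
    )


def random_baseline_study(
    model: GPModel,
    cands: CandidateSet,
    n: int,
    n_sets: int,
    set_size: int,
    seed: int,
    reference: Design | None = None,
    sd: float = 0.1,
    sigma2_known: bool = False,
) -> dict:
    """Distribution of min-over-a-set M_EK for random design sets.

    Each of ``n_sets`` sets holds ``set_size`` perturbed-Latin-hypercube
    designs; the study reports the empirical distribution of the set minima
    and, when a reference design is given, the fraction of sets whose minimum
    exceeds the reference M_EK.
    """
    rng = np.random.default_rng(seed)
    minima = np.empty(n_sets)
    for i in range(n_sets):
        vals = [
            mek(perturbed_lh_sample(n, sd, rng), model, cands, sigma2_known).value
            for _ in range(set_size)
        ]
        minima[i] = min(vals)
    out = {"minima": minima, "n_sets": n_sets, "set_size": set_size, "seed": seed}
    if reference is not None:
        ref = mek(reference, model, cands, sigma2_known).value
        out["reference_mek"] = ref
        out["fraction_beaten"] = float(np.mean(minima > ref))
    return out


def scatter_study(
    model: GPModel,
    cands: CandidateSet,
    n: int,
    n_designs: int,
    sd: float,
    seed: int,
    alpha: float = 0.75,
    sigma2_known: bool = False,
) -> pd.DataFrame:
    """Criterion scatter over random perturbed-Lh designs: both log-det
    criteria, J_alpha and M_EK per design (one row each)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_designs):
        d = perturbed_lh_sample(n, sd, rng)
        lb, ln = criterion_pair(d, model)
        rows.append(
            {
                "design": i,
                "c_beta": lb,
                "c_nu": ln,
                "j_alpha": alpha * lb + (1 - alpha) * ln,
                "mek": mek(d, model, cands, sigma2_known).value,
            }
        )
    return pd.DataFrame(rows)
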