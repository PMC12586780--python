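"""Phylogenetically informed allometry of heat transfer coefficients.

Heat transfer coefficients compiled across fish species scale with body
mass, and species sharing ancestry cannot be treated as independent data
points.  The comparative model here is a Gaussian mixed model on
log10-transformed coefficients,

    log10(k) = X beta + u + s + eps,

with a phylogenetic species effect u ~ N(0, sigma_p^2 A) (A the Brownian
expectation of trait covariance on an ultrametric tree), an independent
species effect s ~ N(0, sigma_s^2 I) absorbing intraspecific replicate
structure, and residual eps ~ N(0, sigma_e^2 I) per individual.  Fixed
effects are log10 body mass, regional endothermy, and optionally their
interaction.  Because divergence times are unavailable, branch lengths are
assigned by Grafen's method (node height = descendant tip count minus one,
scaled to unit root height), which makes the tree ultrametric with unit
root-to-tip depth.

The posterior is sampled by a blocked Gibbs sampler (all conditionals are
conjugate for a Gaussian response): diffuse normal priors on beta
(variance 1e8) and inverse-gamma(0.001, 0.001) priors on the three
variances.  Models with different fixed-effect structure are ranked by
DIC computed from the conditional deviance (random effects in focus).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

FORMULAS = ("mass", "mass+endo", "mass*endo")
RESPONSES = ("k_warm", "k_cool", "ratio")

#: required columns of a species-coefficient table
SPECIES_COLUMNS = ["species", "individual", "mass_kg", "k_warm", "k_cool", "endothermic"]


# ---------------------------------------------------------------------------
# trees

class PhyloTree:
    """Rooted phylogeny with named tips; thin wrapper around dendropy.

    Branch lengths are optional on input — comparative analyses assign
    Grafen lengths rather than trusting whatever the Newick carried.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip name(s): {dupes}")
        self._tips = labels

    @property
    def tip_names(self) -> list[str]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self._tree.preorder_node_iter() if not n.is_leaf())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a rooted tree with unique tip names."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return PhyloTree(tree)


def read_newick(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def assign_grafen_lengths(tree: PhyloTree) -> PhyloTree:
    """Assign Grafen branch lengths, scaled to unit root-to-tip depth.

    Each node's height is its number of descendant tips minus one; heights
    are divided by the root height and branch lengths set to the height
    difference between parent and child.  The result is ultrametric with
    every tip at depth 1 from the root.
    """
    out = tree.clone()
    t = out.dendropy_tree
    heights: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            ntips = sum(1 for _ in node.leaf_iter())
            heights[node] = float(ntips - 1)
    root_h = heights[t.seed_node]
    if root_h <= 0:
        raise ValueError("tree must have at least two tips")
    for node in t.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (heights[node.parent_node] - heights[node]) / root_h
    t.seed_node.edge.length = None
    return out


def phylo_covariance(tree: PhyloTree) -> pd.DataFrame:
    """Expected Brownian trait covariance between species on the tree.

    Entry (i, j) is the shared root-to-MRCA path length; on a Grafen-scaled
    tree the diagonal is 1.  Returned as a species-by-species DataFrame.
    """
    t = tree.dendropy_tree
    for node in t.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("tree has missing branch lengths; assign them first")
    # root-to-node depths
    depth: dict = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + node.edge.length
    tips = tree.tip_names
    idx = {name: i for i, name in enumerate(tips)}
    n = len(tips)
    cov = np.zeros((n, n))
    # accumulate per internal node: pairs of tips in different child subtrees
    # have that node as MRCA
    for node in t.postorder_node_iter():
        if node.is_leaf():
            cov[idx[node.taxon.label], idx[node.taxon.label]] = depth[node]
            continue
        child_sets = [[lf.taxon.label for lf in ch.leaf_iter()]
                      for ch in node.child_nodes()]
        d = depth[node]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for x in child_sets[a]:
                    for y in child_sets[b]:
                        cov[idx[x], idx[y]] = d
                        cov[idx[y], idx[x]] = d
    return pd.DataFrame(cov, index=tips, columns=tips)


# ---------------------------------------------------------------------------
# species table

def validate_species_table(table: pd.DataFrame, tree: PhyloTree | None = None) -> pd.DataFrame:
    """Validate a per-individual coefficient table (and tree coverage)."""
    missing = [c for c in SPECIES_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"species table missing column(s) {missing}")
    df = table.copy()
    df["endothermic"] = df["endothermic"].astype(bool)
    for col in ("mass_kg", "k_warm", "k_cool"):
        df[col] = pd.to_numeric(df[col])
        if (df[col] <= 0).any():
            raise ValueError(f"{col} must be strictly positive (log10-transformable)")
    if tree is not None:
        absent = sorted(set(df["species"]) - set(tree.tip_names))
        if absent:
            raise ValueError(f"species not in tree: {absent}")
    return df


def read_species_table(path: str | Path, tree: PhyloTree | None = None) -> pd.DataFrame:
    return validate_species_table(pd.read_csv(path), tree)


def write_species_table(table: pd.DataFrame, path: str | Path) -> None:
    table[SPECIES_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MCMC

@dataclass(frozen=True)
class McmcSettings:
    """Chain length controls: total iterations, burn-in, thinning."""

    iterations: int = 20_000
    burn_in: int = 2_000
    thin: int = 20

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


#: chain settings matching the original comparative analysis
FULL_MCMC = McmcSettings(iterations=500_000, burn_in=50_000, thin=500)


@dataclass
class PosteriorFit:
    """Retained Gibbs draws for one response/formula combination."""

    response: str
    formula: str
    coef_names: list[str]
    species: list[str]
    beta: np.ndarray          # (draws, p)
    u: np.ndarray             # (draws, q) phylogenetic species effects
    s: np.ndarray             # (draws, q) iid species effects
    sigma2_phylo: np.ndarray  # (draws,)
    sigma2_species: np.ndarray
    sigma2_resid: np.ndarray
    dic: float
    settings: McmcSettings
    seed: int
    y: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    species_index: np.ndarray = field(repr=False)
    data_hash: str = ""

    @property
    def n_retained(self) -> int:
        return self.beta.shape[0]

    def coef_draws(self, name: str) -> np.ndarray:
        return self.beta[:, self.coef_names.index(name)]

    def slope_draws(self, endothermic: bool) -> np.ndarray:
        """Posterior draws of the log-log mass slope for one group."""
        sl = self.coef_draws("log10_mass")
        if endothermic:
            if "log10_mass:endo" in self.coef_names:
                sl = sl + self.coef_draws("log10_mass:endo")
        return sl

    def intercept_draws(self, endothermic: bool) -> np.ndarray:
        ic = self.coef_draws("intercept")
        if endothermic and "endo" in self.coef_names:
            ic = ic + self.coef_draws("endo")
        return ic

    def group_line(self, endothermic: bool) -> "AllometricLine":
        """Posterior-mean allometric line for one endothermy group."""
        return AllometricLine(
            intercept=float(self.intercept_draws(endothermic).mean()),
            slope=float(self.slope_draws(endothermic).mean()),
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.coef_names):
            d = self.beta[:, j]
            rows.append((name, d.mean(), d.std(ddof=1),
                         np.quantile(d, 0.025), np.quantile(d, 0.975)))
        for name, d in (("sigma2_phylo", self.sigma2_phylo),
                        ("sigma2_species", self.sigma2_species),
                        ("sigma2_resid", self.sigma2_resid)):
            rows.append((name, d.mean(), d.std(ddof=1),
                         np.quantile(d, 0.025), np.quantile(d, 0.975)))
        return pd.DataFrame(rows, columns=["term", "mean", "sd", "q2.5", "q97.5"])

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "formula": self.formula,
            "dic": self.dic,
            "n_retained": self.n_retained,
            "seed": self.seed,
            "settings": {
                "iterations": self.settings.iterations,
                "burn_in": self.settings.burn_in,
                "thin": self.settings.thin,
            },
            "coefficients": self.summary().to_dict(orient="records"),
        }


def _design_matrix(df: pd.DataFrame, formula: str) -> tuple[np.ndarray, list[str]]:
    logm = np.log10(df["mass_kg"].to_numpy(dtype=float))
    endo = df["endothermic"].to_numpy(dtype=float)
    if formula == "mass":
        X = np.column_stack([np.ones_like(logm), logm])
        names = ["intercept", "log10_mass"]
    elif formula == "mass+endo":
        X = np.column_stack([np.ones_like(logm), logm, endo])
        names = ["intercept", "log10_mass", "endo"]
    elif formula == "mass*endo":
        X = np.column_stack([np.ones_like(logm), logm, endo, logm * endo])
        names = ["intercept", "log10_mass", "endo", "log10_mass:endo"]
    else:
        raise ValueError(f"unknown formula {formula!r}; expected one of {FORMULAS}")
    return X, names


def _response_vector(df: pd.DataFrame, response: str) -> np.ndarray:
    if response == "k_warm":
        v = df["k_warm"].to_numpy(dtype=float)
    elif response == "k_cool":
        v = df["k_cool"].to_numpy(dtype=float)
    elif response == "ratio":
        # per-individual ratio, computed before the log transform
        v = df["k_warm"].to_numpy(dtype=float) / df["k_cool"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown response {response!r}; expected one of {RESPONSES}")
    return np.log10(v)


def _hash_data(y: np.ndarray, sp_idx: np.ndarray, response: str) -> str:
    h = hashlib.sha1()
    h.update(response.encode())
    h.update(np.ascontiguousarray(y).tobytes())
    h.update(np.ascontiguousarray(sp_idx).tobytes())
    return h.hexdigest()


def _invgamma_draw(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def fit_phylo_mixed(
    table: pd.DataFrame,
    tree: PhyloTree,
    response: str = "ratio",
    formula: str = "mass*endo",
    mcmc: McmcSettings = McmcSettings(),
    seed: int = 0,
    prior_beta_var: float = 1e8,
    prior_ig: tuple[float, float] = (0.001, 0.001),
) -> PosteriorFit:
    """Fit the phylogenetic mixed model by blocked Gibbs sampling.

    The response (k_warm, k_cool or their per-individual ratio) is
    log10-transformed, as is body mass.  Grafen branch lengths are assigned
    to the tree internally, so any topology-only Newick works.  Draws are
    deterministic given ``seed``.
    """
    df = validate_species_table(table, tree)
    if formula not in FORMULAS:
        raise ValueError(f"unknown formula {formula!r}")
    if "endo" in formula:
        groups = df.groupby("endothermic")["species"].nunique()
        if len(groups) < 2 or (groups < (2 if formula == "mass*endo" else 1)).any():
            raise ValueError(
                "endothermy formulas need species in both groups "
                "(>= 2 per group for the interaction)"
            )
    y = _response_vector(df, response)
    X, coef_names = _design_matrix(df, formula)
    n, p = X.shape

    species = sorted(df["species"].unique())
    q = len(species)
    sp_idx = df["species"].map({s: i for i, s in enumerate(species)}).to_numpy()

    A = phylo_covariance(assign_grafen_lengths(tree)).loc[species, species].to_numpy()
    # guard against numerically singular A (e.g. zero-length internal edges)
    Ainv = np.linalg.inv(A + 1e-10 * np.eye(q))

    counts = np.bincount(sp_idx, minlength=q).astype(float)
    XtX = X.T @ X
    a0, b0 = prior_ig

    rng = np.random.default_rng(seed)
    # initial values: OLS for beta, residual variance split across components
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid0 = y - X @ beta
    v0 = max(float(resid0 @ resid0) / max(n - p, 1), 1e-6)
    s2p = s2s = s2e = v0
    u = np.zeros(q)
    s = np.zeros(q)

    keep = mcmc.n_retained
    B = np.empty((keep, p))
    U = np.empty((keep, q))
    S = np.empty((keep, q))
    V = np.empty((keep, 3))
    k = 0
    Ip = np.eye(p)

    for it in range(mcmc.iterations):
        w = u[sp_idx] + s[sp_idx]
        # beta | rest
        prec = XtX / s2e + Ip / prior_beta_var
        L = np.linalg.cholesky(prec)
        rhs = X.T @ (y - w) / s2e
        mean = np.linalg.solve(prec, rhs)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)
        xb = X @ beta
        # u | rest (phylogenetic species effects)
        r = y - xb - s[sp_idx]
        t_sum = np.bincount(sp_idx, weights=r, minlength=q)
        prec_u = np.diag(counts / s2e) + Ainv / s2p
        Lu = np.linalg.cholesky(prec_u)
        mean_u = np.linalg.solve(prec_u, t_sum / s2e)
        u = mean_u + np.linalg.solve(Lu.T, rng.standard_normal(q))
        # s | rest (iid species effects)
        r = y - xb - u[sp_idx]
        t_sum = np.bincount(sp_idx, weights=r, minlength=q)
        prec_s = counts / s2e + 1.0 / s2s
        mean_s = (t_sum / s2e) / prec_s
        s = mean_s + rng.standard_normal(q) / np.sqrt(prec_s)
        # variances | rest
        s2p = _invgamma_draw(rng, a0 + q / 2.0, b0 + 0.5 * float(u @ Ainv @ u))
        s2s = _invgamma_draw(rng, a0 + q / 2.0, b0 + 0.5 * float(s @ s))
        e = y - xb - u[sp_idx] - s[sp_idx]
        s2e = _invgamma_draw(rng, a0 + n / 2.0, b0 + 0.5 * float(e @ e))

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == mcmc.thin - 1:
            B[k] = beta
            U[k] = u
            S[k] = s
            V[k] = (s2p, s2s, s2e)
            k += 1

    B, U, S, V = B[:k], U[:k], S[:k], V[:k]
    fit = PosteriorFit(
        response=response, formula=formula, coef_names=coef_names, species=species,
        beta=B, u=U, s=S,
        sigma2_phylo=V[:, 0], sigma2_species=V[:, 1], sigma2_resid=V[:, 2],
        dic=math.nan, settings=mcmc, seed=seed,
        y=y, X=X, species_index=sp_idx,
        data_hash=_hash_data(y, sp_idx, response),
    )
    fit.dic = compute_dic(fit)
    return fit


def compute_dic(fit: PosteriorFit) -> float:
    """Deviance information criterion from the retained draws.

    Uses the conditional deviance (random effects in focus):
    D(theta) = -2 log N(y | X beta + u + s, sigma_e^2 I); then
    DIC = Dbar + pD with pD = Dbar - D(theta_bar) at the posterior means.
    """
    if fit.n_retained < 100:
        raise ValueError("need at least 100 retained draws for a stable DIC")
    y, X, sp = fit.y, fit.X, fit.species_index
    n = y.size
    mu = fit.beta @ X.T + (fit.u + fit.s)[:, sp]          # (draws, n)
    resid2 = ((y[None, :] - mu) ** 2).sum(axis=1)
    s2 = fit.sigma2_resid
    dev = n * np.log(2.0 * np.pi * s2) + resid2 / s2
    if not np.all(np.isfinite(dev)):
        raise ValueError("non-finite deviance encountered")
    dbar = float(dev.mean())
    mu_hat = X @ fit.beta.mean(axis=0) + (fit.u.mean(axis=0) + fit.s.mean(axis=0))[sp]
    s2_hat = float(fit.sigma2_resid.mean())
    d_hat = n * math.log(2.0 * math.pi * s2_hat) + float(((y - mu_hat) ** 2).sum()) / s2_hat
    pd_eff = dbar - d_hat
    return dbar + pd_eff


def rank_models(fits: list[PosteriorFit]) -> pd.DataFrame:
    """Rank candidate fixed-effect structures by DIC (ascending).

    All fits must share the response and underlying data; returns a table
    with DIC and the difference to the best model.
    """
    if not fits:
        raise ValueError("no fits to rank")
    ref = fits[0]
    for f in fits[1:]:
        if f.response != ref.response or f.data_hash != ref.data_hash:
            raise ValueError("fits were computed on different responses or data")
    rows = sorted(((f.formula, f.dic) for f in fits), key=lambda r: r[1])
    best = rows[0][1]
    return pd.DataFrame(
        [(fm, dic, dic - best) for fm, dic in rows],
        columns=["formula", "dic", "delta_dic"],
    )


# ---------------------------------------------------------------------------
# allometric lines and contrasts

@dataclass(frozen=True)
class AllometricLine:
    """Power-law line k = 10^intercept * mass^slope (intercept in log10)."""

    intercept: float
    slope: float

    @classmethod
    def from_coefficient(cls, coefficient: float, slope: float) -> "AllometricLine":
        """Build from the multiplicative form k = coefficient * mass^slope."""
        if coefficient <= 0:
            raise ValueError("coefficient must be positive")
        return cls(intercept=math.log10(coefficient), slope=slope)

    @property
    def coefficient(self) -> float:
        return 10.0 ** self.intercept


def predict_k_at_mass(line: AllometricLine, mass: float) -> float:
    """Evaluate an allometric regression line at a body mass (kg)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return line.coefficient * mass ** line.slope


def contrast_at_mass(
    numerator: AllometricLine, denominator: AllometricLine, mass: float
) -> float:
    """Fold-difference between two allometric lines at a body mass.

    The caller chooses the direction; for comparing endothermic against
    ectothermic fishes the convention is endo/ecto for the warming
    coefficient and the warming:cooling ratio, and ecto/endo for the
    cooling coefficient (the direction in which the endothermic trait is
    an advantage).
    """
    return predict_k_at_mass(numerator, mass) / predict_k_at_mass(denominator, mass)
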