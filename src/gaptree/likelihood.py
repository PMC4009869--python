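"""Likelihood computation and optimisation for gap and nucleotide data.

Binary gap characters evolve under the two-state symmetric Markov model
(Cavender-Farris-Neyman, CFN) with equal state frequencies; nucleotides
under GTR.  Both support discrete-Γ rate heterogeneity (category rates =
mean of each quartile) and, for nucleotides, a proportion of invariant
sites.  Because every observable gap character is variable, the CFN
likelihood can be conditioned on variability (the "CFNv" correction,
the binary case of the Mkv acquisition-bias correction): each character's
likelihood is divided by one minus the probability of a constant
character.  The historical invariant-character augmentation procedure —
appending equal numbers of all-0 and all-1 columns until the conditional
likelihood of the observed data is maximised — is provided alongside the
exact correction and validated against it.

All likelihoods are computed by Felsenstein pruning, vectorised over
characters, with per-character rescaling against underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .gap_coding import CharacterDescriptor, GapCharacterMatrix
from .io_formats import Alignment
from .trees import Tree, nni_neighbors, random_topology, star_tree, unroot

CharacterData = Union[GapCharacterMatrix, Alignment]

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Substitution model family plus rate-heterogeneity and correction.

    ``gamma_shape=None`` means rate homogeneity; otherwise a discrete Γ
    with ``n_rate_categories`` equally weighted categories.  ``correction``
    applies only to the binary family: ``conditional`` is the exact
    variable-characters-only conditioning; ``augmentation`` evaluates the
    plain likelihood of the matrix augmented with ``m_added`` constant
    columns (half all-0, half all-1).
    """

    family: str = "cfn"
    gamma_shape: Optional[float] = None
    n_rate_categories: int = 4
    p_invariant: Optional[float] = None
    gtr_exchangeabilities: Optional[np.ndarray] = None  # AC AG AT CG CT GT; GT == 1
    base_frequencies: Optional[np.ndarray] = None
    correction: str = "none"
    m_added: int = 0

    def __post_init__(self):
        if self.family not in ("cfn", "gtr"):
            raise ModelError(f"unknown family {self.family!r}")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ModelError("gamma_shape must be positive")
        if self.correction not in ("none", "conditional", "augmentation"):
            raise ModelError(f"unknown correction {self.correction!r}")
        if self.m_added % 2:
            raise ModelError("m_added must be even (equal all-0 and all-1 columns)")
        if self.family == "cfn":
            if self.p_invariant is not None and self.correction != "none":
                raise ModelError(
                    "p_invariant is unidentifiable under an ascertainment correction"
                )
        if self.gtr_exchangeabilities is not None:
            ex = np.asarray(self.gtr_exchangeabilities, float)
            if ex.shape != (6,) or (ex < 0).any():
                raise ModelError("gtr_exchangeabilities must be 6 non-negative reals")
            object.__setattr__(self, "gtr_exchangeabilities", ex)
        if self.base_frequencies is not None:
            fr = np.asarray(self.base_frequencies, float)
            if fr.shape != (4,) or not np.isclose(fr.sum(), 1.0):
                raise ModelError("base_frequencies must be a 4-simplex")
            object.__setattr__(self, "base_frequencies", fr)
        if self.p_invariant is not None and not (0 <= self.p_invariant < 1):
            raise ModelError("p_invariant must be in [0, 1)")

    @property
    def n_states(self) -> int:
        return 2 if self.family == "cfn" else 4

    def frequencies(self) -> np.ndarray:
        if self.family == "cfn":
            return np.array([0.5, 0.5])
        if self.base_frequencies is None:
            return np.full(4, 0.25)
        return self.base_frequencies

    def exchangeabilities(self) -> np.ndarray:
        if self.gtr_exchangeabilities is None:
            return np.ones(6)
        return self.gtr_exchangeabilities


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rate of each of ``ncat`` equal-probability Γ(α, α) quartiles
    (mean 1 overall)."""
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    return (upper - lower) * ncat


def cfn_prob(t: float) -> np.ndarray:
    """2x2 transition probabilities of the CFN model at branch length
    ``t`` (expected changes per character)."""
    if t < 0:
        raise ModelError("branch length must be non-negative")
    diff = (1.0 - np.exp(-2.0 * t)) / 2.0
    same = 1.0 - diff
    return np.array([[same, diff], [diff, same]])


def _gtr_eigen(model: ModelSpec):
    freqs = np.clip(model.frequencies(), 1e-8, None)
    freqs = freqs / freqs.sum()
    ex = np.clip(model.exchangeabilities(), 1e-8, 1e8)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    Q = np.zeros((4, 4))
    for (i, j), s in zip(pairs, ex):
        Q[i, j] = s * freqs[j]
        Q[j, i] = s * freqs[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    Q /= mu
    # symmetrise: B = D^{1/2} Q D^{-1/2} with D = diag(freqs)
    sq = np.sqrt(freqs)
    B = (Q * sq[:, None]) / sq[None, :]
    lam, U = np.linalg.eigh((B + B.T) / 2.0)
    left = U.T * sq[None, :]
    right = U / sq[:, None]
    return lam, right, left


def _transition_matrices(model: ModelSpec, lengths: np.ndarray) -> np.ndarray:
    """P matrices for every (rate category, edge): shape (ncat, nedge, s, s)."""
    rates = (
        discrete_gamma_rates(model.gamma_shape, model.n_rate_categories)
        if model.gamma_shape is not None
        else np.ones(1)
    )
    t = rates[:, None] * lengths[None, :]
    if model.family == "cfn":
        diff = (1.0 - np.exp(-2.0 * t)) / 2.0
        same = 1.0 - diff
        P = np.empty(t.shape + (2, 2))
        P[..., 0, 0] = same
        P[..., 1, 1] = same
        P[..., 0, 1] = diff
        P[..., 1, 0] = diff
        return P
    lam, right, left = _gtr_eigen(model)
    expl = np.exp(t[..., None] * lam)  # (ncat, nedge, 4)
    P = np.einsum("ik,cek,kj->ceij", right, expl, left)
    return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# tip partials and compiled trees


def tip_partials(data: CharacterData) -> tuple[list[str], np.ndarray]:
    """(taxa, indicator array of shape (ntaxa, nstates, nchar)); missing
    cells are all-ones (uninformative)."""
    if isinstance(data, GapCharacterMatrix):
        n, m = data.n_taxa, data.n_characters
        out = np.zeros((n, 2, m))
        out[:, 0, :] = (data.states == 0) | (data.states == -1)
        out[:, 1, :] = (data.states == 1) | (data.states == -1)
        return list(data.taxa), out
    n, m = data.n_taxa, data.n_columns
    out = np.zeros((n, 4, m))
    for i, seq in enumerate(data.sequences):
        for j, c in enumerate(seq):
            for s in _IUPAC_SETS[c]:
                out[i, _NUC_INDEX[s], j] = 1.0
    return list(data.taxa), out


class _Compiled:
    """Array form of a tree for repeated pruning: postorder node list with
    child indices and an edge-length vector."""

    def __init__(self, tree: Tree, taxa: list[str]):
        self.nodes = list(tree.postorder())
        self.index = {id(n): k for k, n in enumerate(self.nodes)}
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.lengths = np.array([n.length for n in self.nodes])
        taxon_row = {t: i for i, t in enumerate(taxa)}
        self.tip_rows = {}
        for k, n in enumerate(self.nodes):
            if n.is_leaf:
                if n.label not in taxon_row:
                    raise ModelError(f"tip {n.label!r} absent from data")
                self.tip_rows[k] = taxon_row[n.label]

    def write_back(self) -> None:
        for n, ln in zip(self.nodes, self.lengths):
            n.length = float(ln)


def _site_log_likelihoods(
    compiled: _Compiled,
    tips: np.ndarray,
    model: ModelSpec,
    rate_multiplier: float = 1.0,
) -> np.ndarray:
    """Per-character log-likelihoods, Γ-averaged and invariant-mixed."""
    ncat = model.n_rate_categories if model.gamma_shape is not None else 1
    s = model.n_states
    nchar = tips.shape[2]
    P = _transition_matrices(model, compiled.lengths * rate_multiplier)
    partials: list[Optional[np.ndarray]] = [None] * len(compiled.nodes)
    log_scale = np.zeros(nchar)
    for k, children in enumerate(compiled.children):
        if not children:
            partials[k] = np.broadcast_to(
                tips[compiled.tip_rows[k]][None, :, :], (ncat, s, nchar)
            )
            continue
        acc = np.ones((ncat, s, nchar))
        for c in children:
            msg = np.einsum("cij,cjn->cin", P[:, c], partials[c])
            acc = acc * msg
            partials[c] = None
        mx = acc.max(axis=(0, 1))
        tiny = mx < 1e-120
        if tiny.any():
            scale = np.where(tiny & (mx > 0), mx, 1.0)
            acc = acc / scale[None, None, :]
            log_scale += np.log(scale)
        partials[k] = acc
    freqs = model.frequencies()
    root = partials[-1]
    site = np.einsum("i,cin->cn", freqs, root).mean(axis=0)
    with np.errstate(divide="ignore"):
        log_site = np.log(site) + log_scale
        if model.p_invariant:
            inv = _invariant_site_likelihood(compiled, tips, freqs)
            log_var = np.log1p(-model.p_invariant) + log_site
            with np.errstate(divide="ignore"):
                log_inv = np.log(model.p_invariant * inv)
            log_site = np.logaddexp(log_var, log_inv)
    return log_site


def _invariant_site_likelihood(
    compiled: _Compiled, tips: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    prod = np.ones((len(freqs), tips.shape[2]))
    for k in compiled.tip_rows.values():
        prod *= tips[k]
    return freqs @ prod


def _constant_pattern_probability(
    compiled: _Compiled, model: ModelSpec, n_taxa: int, rate_multiplier: float = 1.0
) -> float:
    """Probability that a character is constant (all tips identical), the
    normaliser of the conditional (variable-characters-only) likelihood."""
    s = model.n_states
    const_tips = np.zeros((n_taxa, s, s))
    for state in range(s):
        const_tips[:, state, state] = 1.0
    log_site = _site_log_likelihoods(compiled, const_tips, model, rate_multiplier)
    return float(np.exp(log_site).sum())


def _augment(matrix: GapCharacterMatrix, m_added: int) -> GapCharacterMatrix:
    half = m_added // 2
    n = matrix.n_taxa
    zeros = np.zeros((n, half), dtype=np.int8)
    ones = np.ones((n, half), dtype=np.int8)
    extra = [
        CharacterDescriptor("augmented_invariant", -1 - i, -i, 1)
        for i in range(m_added)
    ]
    return GapCharacterMatrix(
        list(matrix.taxa),
        list(matrix.characters) + extra,
        np.concatenate([matrix.states, zeros, ones], axis=1),
    )


def log_likelihood(
    tree: Tree,
    data: CharacterData,
    model: ModelSpec,
    rate_multiplier: float = 1.0,
) -> float:
    """Log-likelihood of ``data`` on ``tree`` under ``model``.

    ``correction="conditional"`` divides every character's likelihood by
    the probability of a variable character; ``correction="augmentation"``
    scores the matrix augmented with ``model.m_added`` constant columns
    under the plain model.
    """
    if model.family == "cfn" and not isinstance(data, GapCharacterMatrix):
        raise ModelError("cfn model requires a binary character matrix")
    if model.family == "gtr" and not isinstance(data, Alignment):
        raise ModelError("gtr model requires a nucleotide alignment")
    if model.correction == "augmentation":
        data = _augment(data, model.m_added)
    taxa, tips = tip_partials(data)
    compiled = _Compiled(tree, taxa)
    log_site = _site_log_likelihoods(compiled, tips, model, rate_multiplier)
    lnl = float(log_site.sum())
    if not np.isfinite(lnl):
        warnings.warn("zero-likelihood character pattern; -inf returned")
        return -np.inf
    if model.correction == "conditional":
        p_const = _constant_pattern_probability(
            compiled, model, len(taxa), rate_multiplier
        )
        lnl -= tips.shape[2] * np.log1p(-p_const)
    return lnl


# ---------------------------------------------------------------------------
# optimisation


@dataclass
class FitResult:
    tree: Tree
    model: ModelSpec
    lnl: float
    converged: bool
    n_rounds: int = 0


def _empirical_frequencies(data: Alignment) -> np.ndarray:
    counts = np.zeros(4)
    for seq in data.sequences:
        for c in seq:
            if c in _NUC_INDEX:
                counts[_NUC_INDEX[c]] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def optimize_branch_lengths_and_params(
    tree: Tree,
    data: CharacterData,
    model: ModelSpec,
    optimize_model: bool = True,
    tol: float = 1e-6,
    max_rounds: int = 30,
    max_branch_length: float = 40.0,
) -> FitResult:
    """Coordinate-wise maximum likelihood on a fixed topology: Brent line
    searches per branch, then the model parameters, iterated until the
    relative log-likelihood gain falls below ``tol``."""
    tree = unroot(tree)
    if model.family == "gtr" and model.base_frequencies is None:
        model = replace(model, base_frequencies=_empirical_frequencies(data))
    work = model
    if work.correction == "augmentation":
        data = _augment(data, work.m_added)
        work = replace(work, correction="none", m_added=0)
    taxa, tips = tip_partials(data)
    compiled = _Compiled(tree, taxa)
    n_taxa = len(compiled.tip_rows)

    def lnl_current(m: ModelSpec) -> float:
        value = float(_site_log_likelihoods(compiled, tips, m).sum())
        if m.correction == "conditional":
            value -= tips.shape[2] * np.log1p(
                -_constant_pattern_probability(compiled, m, n_taxa)
            )
        return value

    # keep supplied positive lengths, nudge zeros off the boundary
    compiled.lengths[compiled.lengths <= 0] = 0.05
    compiled.lengths[-1] = 0.0  # root has no edge

    current = lnl_current(work)
    n_edges = len(compiled.lengths) - 1
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        previous = current
        for e in range(n_edges):
            def neg(x, e=e):
                compiled.lengths[e] = x
                return -lnl_current(work)

            res = optimize.minimize_scalar(
                neg,
                bounds=(1e-9, max_branch_length),
                method="bounded",
                options={"xatol": 1e-7},
            )
            best_x = float(res.x)
            compiled.lengths[e] = best_x
            current = -float(res.fun)
        if optimize_model:
            work, current = _optimize_model_params(work, lnl_current, current)
        if current < previous - 1e-9:  # guard: never accept a decrease
            current = previous
        if abs(current - previous) <= tol * max(1.0, abs(previous)):
            converged = True
            break
    if not converged:
        warnings.warn("branch-length optimisation stopped at max_rounds")
    compiled.write_back()
    out_model = work
    if model.correction == "augmentation":
        out_model = replace(work, correction="augmentation", m_added=model.m_added)
    return FitResult(tree, out_model, current, converged, rounds)


def _optimize_model_params(model: ModelSpec, lnl_fn, current: float):
    if model.gamma_shape is not None:
        def neg_alpha(loga):
            return -lnl_fn(replace(model, gamma_shape=float(np.exp(loga))))

        res = optimize.minimize_scalar(
            neg_alpha, bounds=(np.log(0.02), np.log(100.0)), method="bounded",
            options={"xatol": 1e-4},
        )
        if -res.fun > current:
            model = replace(model, gamma_shape=float(np.exp(res.x)))
            current = -float(res.fun)
    if model.p_invariant is not None:
        def neg_pinv(p):
            return -lnl_fn(replace(model, p_invariant=float(p)))

        res = optimize.minimize_scalar(
            neg_pinv, bounds=(0.0, 0.95), method="bounded", options={"xatol": 1e-5}
        )
        if -res.fun > current:
            model = replace(model, p_invariant=float(res.x))
            current = -float(res.fun)
    if model.family == "gtr":
        ex = model.exchangeabilities()

        def neg_ex(logex):
            full = np.concatenate([np.exp(logex), [1.0]])
            return -lnl_fn(replace(model, gtr_exchangeabilities=full))

        res = optimize.minimize(
            neg_ex,
            np.log(np.clip(ex[:5] / ex[5], 1e-3, 1e3)),
            method="L-BFGS-B",
            bounds=[(np.log(1e-3), np.log(1e3))] * 5,
            options={"maxiter": 40},
        )
        if -res.fun > current:
            full = np.concatenate([np.exp(res.x), [1.0]])
            model = replace(model, gtr_exchangeabilities=full)
            current = -float(res.fun)
    return model, current


# ---------------------------------------------------------------------------
# invariant-character augmentation


def estimate_invariant_augmentation(
    data: GapCharacterMatrix,
    tree: Tree,
    grid: Optional[Sequence[int]] = None,
    model: Optional[ModelSpec] = None,
    refine: bool = True,
    optimize_model: bool = True,
    tol: float = 1e-6,
):
    """Estimate how many unobservable invariant characters to append.

    For each even ``m`` in the grid the matrix is augmented with ``m/2``
    all-0 and ``m/2`` all-1 columns and fitted under the plain model; the
    augmentation is scored by the conditional likelihood of the observed
    characters at those fitted parameters.  Returns ``(m_star, table)``
    where the table holds (m, conditional lnL, plain lnL, fit).
    """
    import pandas as pd

    if grid is None:
        grid = [0, 2, 20, 200, 2000, 20000]
    grid = sorted({int(m) for m in grid})
    if not grid:
        raise ModelError("empty augmentation grid")
    if any(m < 0 or m % 2 for m in grid):
        raise ModelError("grid entries must be even non-negative integers")
    model = model or ModelSpec(family="cfn", gamma_shape=1.0)

    rows = {}

    def evaluate(m: int):
        if m in rows:
            return rows[m]["conditional_lnl"]
        fit = optimize_branch_lengths_and_params(
            tree.copy(),
            data,
            replace(model, correction="augmentation", m_added=m),
            optimize_model=optimize_model,
            tol=tol,
        )
        cond_model = replace(fit.model, correction="conditional", m_added=0)
        cond = log_likelihood(fit.tree, data, cond_model)
        rows[m] = {
            "m": m,
            "conditional_lnl": cond,
            "augmented_lnl": fit.lnl,
            "fit": fit,
        }
        return cond

    for m in grid:
        evaluate(m)

    def argmax() -> int:
        return max(rows, key=lambda m: rows[m]["conditional_lnl"])

    if refine:
        for _ in range(8):
            ms = sorted(rows)
            best = argmax()
            i = ms.index(best)
            lo = ms[i - 1] if i > 0 else best
            hi = ms[i + 1] if i < len(ms) - 1 else best * 2
            candidates = {
                2 * round((lo + best) / 4),
                2 * round((best + hi) / 4),
            } - set(ms)
            candidates = {c for c in candidates if c >= 0}
            if not candidates:
                break
            for c in sorted(candidates):
                evaluate(c)

    best = argmax()
    values = [r["conditional_lnl"] for r in rows.values()]
    if np.ptp(values) < 1e-9:
        warnings.warn("conditional likelihood flat in m; smallest m returned")
        best = min(rows)
    table = pd.DataFrame(
        [
            {k: v for k, v in r.items() if k != "fit"}
            for r in sorted(rows.values(), key=lambda r: r["m"])
        ]
    )
    return best, table, rows[best]["fit"]


# ---------------------------------------------------------------------------
# partitioned models


@dataclass
class Partition:
    data: CharacterData
    model: ModelSpec
    rate_multiplier: float = 1.0


@dataclass
class PartitionedModel:
    """Shared topology and branch lengths; each partition scales them by
    its own rate multiplier (the first multiplier is fixed at 1 for
    identifiability)."""

    partitions: list[Partition]

    def __post_init__(self):
        if not self.partitions:
            raise ModelError("no partitions")
        tip_sets = [set(_data_taxa(p.data)) for p in self.partitions]
        if any(t != tip_sets[0] for t in tip_sets):
            raise ModelError("partitions reference different tip sets")
        if any(p.rate_multiplier <= 0 for p in self.partitions):
            raise ModelError("rate multipliers must be positive")


def _data_taxa(data: CharacterData) -> list[str]:
    return list(data.taxa)


def combined_log_likelihood(partitioned: PartitionedModel, tree: Tree) -> float:
    """Sum of per-partition log-likelihoods with shared branch lengths
    scaled by each partition's rate multiplier."""
    return sum(
        log_likelihood(tree, p.data, p.model, rate_multiplier=p.rate_multiplier)
        for p in partitioned.partitions
    )


def optimize_partitioned(
    tree: Tree,
    partitioned: PartitionedModel,
    optimize_model: bool = True,
    tol: float = 1e-6,
    max_rounds: int = 20,
) -> tuple[Tree, PartitionedModel, float]:
    """Coordinate-wise fit of shared branch lengths, per-partition rate
    multipliers (first fixed at 1) and model parameters."""
    tree = unroot(tree.copy())
    parts = [replace(p) for p in partitioned.partitions]
    compiled_data = []
    for p in parts:
        data, work = p.data, p.model
        if work.correction == "augmentation":
            data = _augment(data, work.m_added)
            work = replace(work, correction="none", m_added=0)
        taxa, tips = tip_partials(data)
        compiled_data.append((taxa, tips, work))
    compiled = _Compiled(tree, compiled_data[0][0])
    compiled.lengths[compiled.lengths <= 0] = 0.05
    compiled.lengths[-1] = 0.0
    # per-partition compiled views share the same length vector
    views = []
    for taxa, tips, work in compiled_data:
        view = _Compiled(tree, taxa)
        view.lengths = compiled.lengths  # shared storage
        views.append((view, tips, work))

    def part_lnl(i: int, mult: float, m: Optional[ModelSpec] = None) -> float:
        view, tips, work = views[i]
        m = m or work
        value = float(_site_log_likelihoods(view, tips, m, mult).sum())
        if m.correction == "conditional":
            value -= tips.shape[2] * np.log1p(
                -_constant_pattern_probability(view, m, len(view.tip_rows), mult)
            )
        return value

    def total() -> float:
        return sum(part_lnl(i, parts[i].rate_multiplier) for i in range(len(parts)))

    current = total()
    n_edges = len(compiled.lengths) - 1
    for _ in range(max_rounds):
        previous = current
        for e in range(n_edges):
            def neg(x, e=e):
                compiled.lengths[e] = x
                return -total()

            res = optimize.minimize_scalar(
                neg, bounds=(1e-9, 40.0), method="bounded", options={"xatol": 1e-7}
            )
            compiled.lengths[e] = float(res.x)
            current = -float(res.fun)
        for i in range(1, len(parts)):
            def neg_mult(logm, i=i):
                others = sum(
                    part_lnl(j, parts[j].rate_multiplier)
                    for j in range(len(parts))
                    if j != i
                )
                return -(others + part_lnl(i, float(np.exp(logm))))

            res = optimize.minimize_scalar(
                neg_mult, bounds=(np.log(1e-3), np.log(1e3)), method="bounded",
                options={"xatol": 1e-5},
            )
            parts[i].rate_multiplier = float(np.exp(res.x))
            current = -float(res.fun)
        if optimize_model:
            for i, (view, tips, work) in enumerate(views):
                def lnl_fn(m, i=i):
                    others = sum(
                        part_lnl(j, parts[j].rate_multiplier)
                        for j in range(len(parts))
                        if j != i
                    )
                    return others + part_lnl(i, parts[i].rate_multiplier, m)

                new_model, current = _optimize_model_params(work, lnl_fn, current)
                views[i] = (view, tips, new_model)
        if abs(current - previous) <= tol * max(1.0, abs(previous)):
            break
    compiled.write_back()
    for p, (view, tips, work) in zip(parts, views):
        if p.model.correction == "augmentation":
            p.model = replace(work, correction="augmentation", m_added=p.model.m_added)
        else:
            p.model = work
    return tree, PartitionedModel(parts), current


# ---------------------------------------------------------------------------
# tree search


@dataclass
class MLSearchConfig:
    restarts: int = 2
    seed: int = 0
    swap: str = "nni"
    tol: float = 1e-5
    optimize_model: bool = True


def _neighbor_joining_start(data: CharacterData) -> Tree:
    """Neighbour-joining starting tree from pairwise mismatch distances."""
    import skbio

    taxa = _data_taxa(data)
    if isinstance(data, GapCharacterMatrix):
        states = data.states.astype(float)
        states[data.states == -1] = np.nan
        rows = states
    else:
        conv = {"A": 0.0, "C": 1.0, "G": 2.0, "T": 3.0}
        rows = np.array(
            [[conv.get(c, np.nan) for c in seq] for seq in data.sequences]
        )
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(rows[i]) & ~np.isnan(rows[j])
            p = float((rows[i][ok] != rows[j][ok]).mean()) if ok.sum() else 0.5
            D[i, j] = D[j, i] = max(p, 1e-6) + 1e-6
    dm = skbio.DistanceMatrix(D, ids=taxa)
    nj_tree = skbio.tree.nj(dm)
    return unroot(Tree.from_newick(str(nj_tree)))


def ml_search(
    data: Union[CharacterData, PartitionedModel],
    model: Optional[ModelSpec] = None,
    config: Optional[MLSearchConfig] = None,
) -> FitResult:
    """Hill-climbing ML topology search with branch-length re-optimisation.

    Multi-start: a neighbour-joining tree plus random topologies.  At each
    step all NNI neighbours are scored (branch lengths carried over) and
    the best is fully re-optimised; the move is kept only if it improves
    the log-likelihood.  Deterministic given ``config.seed``."""
    config = config or MLSearchConfig()
    partitioned = isinstance(data, PartitionedModel)
    if not partitioned and model is None:
        raise ModelError("model required for single-matrix search")
    rng = np.random.default_rng(config.seed)
    first = data.partitions[0].data if partitioned else data
    taxa = _data_taxa(first)

    def fit(tree: Tree) -> FitResult:
        if partitioned:
            t, pm, lnl = optimize_partitioned(
                tree, data, optimize_model=config.optimize_model, tol=config.tol
            )
            return FitResult(t, pm, lnl, True)
        return optimize_branch_lengths_and_params(
            tree, data, model, optimize_model=config.optimize_model, tol=config.tol
        )

    def quick_lnl(tree: Tree, fitted_model) -> float:
        """Cheap neighbour score: a couple of coordinate rounds from the
        carried-over branch lengths."""
        if partitioned:
            pm = fitted_model if isinstance(fitted_model, PartitionedModel) else data
            _, _, lnl = optimize_partitioned(
                tree, pm, optimize_model=False, tol=1e-3, max_rounds=2
            )
            return lnl
        m = fitted_model if isinstance(fitted_model, ModelSpec) else model
        return optimize_branch_lengths_and_params(
            tree, data, m, optimize_model=False, tol=1e-3, max_rounds=2
        ).lnl

    if len(taxa) < 4:
        tree = star_tree(taxa)
        return fit(tree)

    starts = [_neighbor_joining_start(first)]
    for _ in range(max(0, config.restarts - 1)):
        starts.append(random_topology(taxa, rng))

    best: Optional[FitResult] = None
    for start in starts:
        result = fit(start)
        improved = True
        while improved:
            improved = False
            neighbors = list(nni_neighbors(result.tree))
            scored = sorted(
                ((quick_lnl(nb, result.model), k) for k, nb in enumerate(neighbors)),
                reverse=True,
            )
            # fully refit every neighbour whose cheap score could plausibly
            # beat the current tree (partial fits understate the optimum)
            candidates = [k for q, k in scored if q > result.lnl - 3.0][:6]
            if not candidates and scored:
                candidates = [scored[0][1]]
            for k in candidates:
                candidate = fit(neighbors[k])
                if candidate.lnl > result.lnl + 1e-9:
                    result = candidate
                    improved = True
                    break
        if best is None or result.lnl > best.lnl:
            best = result
    return best


def ml_bootstrap(
    data: Union[CharacterData, PartitionedModel],
    replicates: int,
    model: Optional[ModelSpec] = None,
    config: Optional[MLSearchConfig] = None,
    seed: Optional[int] = None,
):
    """ML bootstrap: characters resampled with replacement (independently
    within each partition), a tree search per replicate, bipartition
    frequencies over replicate trees."""
    from .parsimony import _resample
    from .treecompare import SupportTable

    if replicates < 1:
        raise ModelError("replicates must be >= 1")
    config = config or MLSearchConfig(restarts=1)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    partitioned = isinstance(data, PartitionedModel)
    counts: dict[frozenset, int] = {}
    taxa_set: set = set()
    for rep in range(replicates):
        if partitioned:
            parts = []
            for p in data.partitions:
                n = (
                    p.data.n_characters
                    if isinstance(p.data, GapCharacterMatrix)
                    else p.data.n_columns
                )
                idx = rng.integers(0, n, size=n)
                parts.append(
                    Partition(_resample(p.data, idx), p.model, p.rate_multiplier)
                )
            resampled = PartitionedModel(parts)
        else:
            n = (
                data.n_characters
                if isinstance(data, GapCharacterMatrix)
                else data.n_columns
            )
            idx = rng.integers(0, n, size=n)
            resampled = _resample(data, idx)
        rep_config = replace(config, seed=int(rng.integers(2**31 - 1)))
        result = ml_search(resampled, model, rep_config)
        taxa_set = set(result.tree.taxa)
        for b in result.tree.bipartitions():
            counts[b] = counts.get(b, 0) + 1
    support = {b: c / replicates for b, c in counts.items()}
    return SupportTable(
        support,
        taxa=frozenset(taxa_set),
        provenance={"method": "ml_bootstrap", "replicates": replicates, "seed": seed},
    )
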