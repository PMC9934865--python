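"""Paired nuclear / whole-cell count simulation from two-compartment kinetics.

Each gene g follows a linear birth-export-decay model over latent
differentiation time t in [0, 1]:

    dn/dt = alpha_g(t) - beta_g * n        (nuclear pool)
    dc/dt = beta_g * n - delta_g(t) * c    (cytoplasmic pool)

with piecewise-constant transcription alpha_g(t) and cytoplasmic decay
delta_g(t), solved in closed form on each constant piece.  The nuclear
modality samples counts from n alone (snRNA-seq style); the whole-cell
modality samples from n + c (scRNA-seq style).

Transcription programs emulate a differentiating germline: an early
(mitotic-stage) program, a burst of spermatocyte-like transcription that
shuts down before the spermatid-like stages, gene-specific cytoplasmic
behavior after shutdown (fast decay, late degradation, or stable
perdurance), a small set of genes transcribed de novo in late stages, an
"X"-tagged module silenced mid-axis and a "Y"-tagged module activated
mid-axis.  Sequencing depth rises from under 5,000 to over 30,000 expected
UMIs through the spermatocyte-like stages, then collapses (sharply for the
nuclear modality, buffered by the cytoplasm for whole cells).

Because counts are depth-normalized downstream, "flat" genes are
calibrated to hold a constant *share* of their modality's transcript pool
(not a constant rate): a constant-rate gene would still appear dynamic
after compositional normalization whenever other programs surge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CountMatrix, ValidationError, make_cell_table, make_gene_table

TRUE_CLASSES = (
    "early_program",
    "spermatocyte_transient",
    "spermatocyte_perdurant_degraded",
    "spermatocyte_perdurant_stable",
    "spermatid_transcribed",
    "flat",
)

# stage boundaries on latent time, loosely mirroring
# spermatogonia -> spermatocytes -> early spermatids -> late spermatids
STAGE_BREAKS = (0.2, 0.45, 0.65)
STAGE_NAMES = ("spermatogonia", "spermatocyte", "early_spermatid", "late_spermatid")


@dataclass
class KineticParams:
    """Piecewise-constant kinetic program for one gene.

    ``alpha_breaks``/``alpha_rates`` define transcription: rate
    ``alpha_rates[i]`` applies on ``[alpha_breaks[i], alpha_breaks[i+1])``
    with breaks spanning [0, 1].  ``delta_breaks``/``delta_rates`` do the
    same for cytoplasmic decay.  ``beta`` is the constant nuclear export
    rate, ``theta`` the negative-binomial overdispersion (var = mu +
    mu^2/theta), and ``n0``/``c0`` the pool sizes at t = 0 (genes already
    transcribing before the observation window start above zero).
    """

    gene_id: str
    alpha_breaks: np.ndarray
    alpha_rates: np.ndarray
    beta: float
    delta_breaks: np.ndarray
    delta_rates: np.ndarray
    theta: float = 10.0
    chromosome: str = "autosome"
    true_class: str = "flat"
    n0: float = 0.0
    c0: float = 0.0

    def __post_init__(self) -> None:
        self.alpha_breaks = np.asarray(self.alpha_breaks, dtype=float)
        self.alpha_rates = np.asarray(self.alpha_rates, dtype=float)
        self.delta_breaks = np.asarray(self.delta_breaks, dtype=float)
        self.delta_rates = np.asarray(self.delta_rates, dtype=float)
        if self.beta <= 0:
            raise ValidationError(f"{self.gene_id}: export rate beta must be > 0")
        for name, arr in (("alpha", self.alpha_rates), ("delta", self.delta_rates)):
            if (arr < 0).any():
                raise ValidationError(f"{self.gene_id}: negative {name} rate")
        if self.theta <= 0:
            raise ValidationError(f"{self.gene_id}: theta must be > 0")
        if self.n0 < 0 or self.c0 < 0:
            raise ValidationError(f"{self.gene_id}: negative initial pools")
        for br in (self.alpha_breaks, self.delta_breaks):
            if br[0] != 0.0 or (np.diff(br) <= 0).any() or (br > 1).any():
                raise ValidationError(
                    f"{self.gene_id}: breakpoints must start at 0, be increasing, lie in [0,1]"
                )
        if self.true_class not in TRUE_CLASSES:
            raise ValidationError(f"unknown true_class {self.true_class!r}")

    def transcription_off_time(self) -> float:
        """Last time transcription switches off, or 1.0 if it never does."""
        active = self.alpha_rates > 1e-12
        if not active.any():
            return 0.0
        if active[-1]:
            return 1.0
        last_on = int(np.max(np.nonzero(active)[0]))
        return float(self.alpha_breaks[last_on + 1])


def _piece_solution(a: float, b: float, d: float, n0: float, c0: float, tau: np.ndarray):
    """Closed-form (n, c) at offsets tau within one constant-rate piece."""
    A = n0 - a / b
    n = a / b + A * np.exp(-b * tau)
    eps = 1e-10
    if d <= eps:
        c = c0 + a * tau + A * (1.0 - np.exp(-b * tau))
    elif abs(d - b) <= eps * max(1.0, b):
        c = a / d + b * A * tau * np.exp(-b * tau) + (c0 - a / d) * np.exp(-d * tau)
    else:
        B = b * A / (d - b)
        c = a / d + B * np.exp(-b * tau) + (c0 - a / d - B) * np.exp(-d * tau)
    return n, c


def kinetic_abundance(params: KineticParams, t: np.ndarray | float):
    """Noiseless nuclear and cytoplasmic abundance at latent times ``t``.

    Solves the two-compartment linear ODE piecewise in closed form, starting
    from ``(params.n0, params.c0)`` at t = 0.  Returns arrays shaped like
    ``t`` (or floats for scalar input).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr < 0).any() or (t_arr > 1 + 1e-9).any():
        raise ValidationError("latent time must lie in [0, 1]")
    breaks = np.unique(
        np.concatenate([params.alpha_breaks, params.delta_breaks, [0.0, 1.0]])
    )
    n_state, c_state = float(params.n0), float(params.c0)
    n_out = np.zeros_like(t_arr)
    c_out = np.zeros_like(t_arr)
    for start, stop in zip(breaks[:-1], breaks[1:]):
        a = params.alpha_rates[
            np.searchsorted(params.alpha_breaks, start, side="right") - 1
        ]
        d = params.delta_rates[
            np.searchsorted(params.delta_breaks, start, side="right") - 1
        ]
        in_piece = (t_arr >= start) & (t_arr < stop)
        if stop >= breaks[-1]:
            in_piece |= t_arr >= stop  # include t == 1 in the final piece
        if in_piece.any():
            n_out[in_piece], c_out[in_piece] = _piece_solution(
                a, params.beta, d, n_state, c_state, t_arr[in_piece] - start
            )
        n_end, c_end = _piece_solution(
            a, params.beta, d, n_state, c_state, np.array([stop - start])
        )
        n_state, c_state = float(n_end[0]), float(c_end[0])
    n_out = np.clip(n_out, 0.0, None)
    c_out = np.clip(c_out, 0.0, None)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(n_out[0]), float(c_out[0])
    return n_out, c_out


def _bump(on: float, off: float, rate: float):
    """alpha program: zero, then ``rate`` on [on, off), then zero."""
    breaks = [0.0]
    rates = []
    if on > 0:
        rates.append(0.0)
        breaks.append(on)
    rates.append(rate)
    if off < 1.0:
        breaks.append(off)
        rates.append(0.0)
    return np.array(breaks), np.array(rates)


def _calibrated_flat_gene(
    gene_id: str,
    rate: float,
    theta: float,
    beta: float,
    tg: np.ndarray,
    env_nuc: np.ndarray,
    env_whole: np.ndarray,
    n_segments: int = 25,
) -> KineticParams:
    """A gene holding a constant share of both modality pools.

    Target trajectories n*(t) proportional to the nuclear envelope and
    (n* + c*)(t) proportional to the whole-cell envelope are converted back
    into a piecewise-constant (alpha, delta) program by inverting the ODE at
    segment midpoints; initial conditions pin the t=0 state.
    """
    q = rate / env_nuc.mean()
    n_target = q * env_nuc
    # inflate the whole-cell share so the cytoplasmic target stays positive
    k_w = q * float(np.max(env_nuc / env_whole)) * 1.1
    c_target = k_w * env_whole - n_target
    dn = np.gradient(n_target, tg)
    dc = np.gradient(c_target, tg)
    edges = np.linspace(0.0, 1.0, n_segments + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    n_mid = np.interp(mids, tg, n_target)
    dn_mid = np.interp(mids, tg, dn)
    dc_mid = np.interp(mids, tg, dc)
    c_mid = np.interp(mids, tg, c_target)
    alpha = np.clip(beta * n_mid + dn_mid, 0.0, None)
    delta = np.clip((beta * n_mid - dc_mid) / np.maximum(c_mid, 1e-9), 0.0, None)
    return KineticParams(
        gene_id=gene_id,
        alpha_breaks=edges[:-1],
        alpha_rates=alpha,
        beta=beta,
        delta_breaks=edges[:-1],
        delta_rates=delta,
        theta=theta,
        chromosome="autosome",
        true_class="flat",
        n0=float(n_target[0]),
        c0=float(max(c_target[0], 0.0)),
    )


def default_gene_params(
    n_genes: int = 300, seed: int = 1, beta: float = 20.0
) -> list[KineticParams]:
    """The default gene census: a differentiating-lineage-like program mix.

    Roughly 20% flat (constant-share) genes, an early mitotic-stage
    program, a large spermatocyte-like program split into fast-decay
    (transient), late-degraded and stable-perdurant cytoplasmic behaviors,
    and ~10% late spermatid-transcribed genes.  A quarter of the transient
    genes carry an "X" tag (silenced by t ~ 0.55); ~30% of the stable genes
    carry a "Y" tag (activated mid-axis, t ~ 0.45, never silenced).
    """
    rng = np.random.default_rng(seed)
    # perduring classes are kept a small minority of the dynamic genes, as
    # they are in real spermatogenesis data; a perdurant-heavy census would
    # also let the DTW consensus absorb the perdurance offset itself
    census = {
        "early_program": 0.15,
        "spermatocyte_transient": 0.40,
        "spermatocyte_perdurant_degraded": 0.07,
        "spermatocyte_perdurant_stable": 0.08,
        "spermatid_transcribed": 0.10,
        "flat": 0.20,
    }
    counts = {k: int(round(v * n_genes)) for k, v in census.items()}
    counts["flat"] += n_genes - sum(counts.values())
    params: list[KineticParams] = []
    flat_specs: list[tuple[str, float, float]] = []
    gid = 0
    for cls, n_cls in counts.items():
        n_x = int(round(0.25 * n_cls)) if cls == "spermatocyte_transient" else 0
        n_y = int(round(0.30 * n_cls)) if cls == "spermatocyte_perdurant_stable" else 0
        for j in range(n_cls):
            gid += 1
            gene_id = f"g{gid:04d}"
            rate = float(rng.lognormal(np.log(40.0), 0.4))
            theta = float(rng.uniform(5.0, 20.0))
            chrom = "autosome"
            if cls == "flat":
                flat_specs.append((gene_id, rate * 0.5, theta))
                continue
            if cls == "early_program":
                off = float(rng.uniform(0.10, 0.17))
                ab, ar = _bump(0.0, off, rate)
                db, dr = np.array([0.0]), np.array([6.0])
                n0 = rate / beta  # already at steady state when the window opens
                c0 = beta * n0 / dr[0]
            elif cls == "spermatocyte_transient":
                on = float(rng.uniform(0.20, 0.26))
                off = float(rng.uniform(0.42, 0.48))
                if j < n_x:  # X-tagged: silenced earlier
                    chrom = "X"
                    on, off = float(rng.uniform(0.16, 0.22)), float(rng.uniform(0.36, 0.42))
                ab, ar = _bump(on, off, rate)
                db, dr = np.array([0.0]), np.array([10.0])
                n0 = c0 = 0.0
            elif cls == "spermatocyte_perdurant_degraded":
                on = float(rng.uniform(0.20, 0.26))
                off = float(rng.uniform(0.42, 0.48))
                ab, ar = _bump(on, off, rate)
                # abrupt degradation staggered across later spermatid stages
                boost = float(rng.uniform(0.70, 0.88))
                db, dr = np.array([0.0, boost]), np.array([0.15, 14.0])
                n0 = c0 = 0.0
            elif cls == "spermatocyte_perdurant_stable":
                on = float(rng.uniform(0.20, 0.26))
                off = float(rng.uniform(0.42, 0.48))
                if j < n_y:  # Y-tagged: mid-onset, never silenced
                    chrom, on, off = "Y", float(rng.uniform(0.32, 0.38)), 1.0
                ab, ar = _bump(on, off, rate)
                db, dr = np.array([0.0]), np.array([0.05])
                n0 = c0 = 0.0
            else:  # spermatid_transcribed: mid-to-late staggered (re)activation
                on = float(rng.uniform(0.60, 0.90))
                ab, ar = _bump(on, 1.0, rate)
                db, dr = np.array([0.0]), np.array([0.5])
                n0 = c0 = 0.0
            params.append(
                KineticParams(
                    gene_id=gene_id, alpha_breaks=ab, alpha_rates=ar, beta=beta,
                    delta_breaks=db, delta_rates=dr, theta=theta, chromosome=chrom,
                    true_class=cls, n0=n0, c0=c0,
                )
            )
    # calibrate flat genes against the non-flat pool envelopes
    tg = np.linspace(0.0, 1.0, 401)
    env_nuc = np.zeros_like(tg)
    env_whole = np.zeros_like(tg)
    for p in params:
        n_ab, c_ab = kinetic_abundance(p, tg)
        env_nuc += n_ab
        env_whole += n_ab + c_ab
    env_nuc = np.maximum(env_nuc, 1e-9)
    env_whole = np.maximum(env_whole, 1e-9)
    for gene_id, rate, theta in flat_specs:
        params.append(
            _calibrated_flat_gene(gene_id, rate, theta, beta, tg, env_nuc, env_whole)
        )
    params.sort(key=lambda p: p.gene_id)
    return params


def nuclear_depth_profile(t: np.ndarray) -> np.ndarray:
    """Expected nuclear UMI total vs latent time: <5k rising to >30k, then collapse."""
    knots_t = np.array([0.0, 0.2, 0.38, 0.45, 0.58, 0.72, 1.0])
    knots_d = np.array([3000, 5000, 25000, 32000, 4000, 1500, 1200], dtype=float)
    return np.interp(t, knots_t, knots_d)


def whole_cell_depth_profile(t: np.ndarray) -> np.ndarray:
    """Expected whole-cell UMI total: cytoplasm buffers the late collapse."""
    knots_t = np.array([0.0, 0.2, 0.4, 0.52, 0.75, 1.0])
    knots_d = np.array([6000, 9000, 28000, 33000, 15000, 8000], dtype=float)
    return np.interp(t, knots_t, knots_d)


def _stage_labels(t: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(np.asarray(STAGE_BREAKS), t, side="right")
    return np.asarray(STAGE_NAMES)[idx]


@dataclass
class SimTruth:
    """Ground truth from a simulation run: per-cell and per-gene tables."""

    cells: dict[str, pd.DataFrame]
    genes: pd.DataFrame


def _sample_counts(
    abundance: np.ndarray,
    depths: np.ndarray,
    size_factors: np.ndarray,
    thetas: np.ndarray,
    rng: np.random.Generator,
) -> sp.csr_matrix:
    """Gene-wise negative binomial counts (gamma-Poisson), genes x cells."""
    col_sums = abundance.sum(axis=0)
    col_sums = np.where(col_sums > 0, col_sums, 1.0)
    mu = abundance / col_sums[None, :] * (depths * size_factors)[None, :]
    lam = rng.gamma(shape=thetas[:, None], scale=np.maximum(mu, 1e-300) / thetas[:, None])
    counts = rng.poisson(np.where(mu > 0, lam, 0.0))
    return sp.csr_matrix(counts)


def simulate_paired_datasets(
    params: list[KineticParams],
    n_cells_per_modality: int = 3000,
    seed: int = 1,
    nuclear_depth=nuclear_depth_profile,
    whole_cell_depth=whole_cell_depth_profile,
):
    """Simulate matched nuclear and whole-cell datasets with ground truth.

    Latent times are sampled uniformly on [0, 1] independently per modality
    (uniform coverage keeps grid smoothing testable; real stage censuses are
    uneven).  Counts are negative binomial around the gene's relative pool
    abundance scaled to the stage-dependent expected depth and a lognormal
    per-cell size factor.  Identical inputs and seed give identical output.

    Returns ``(datasets, truth)`` where ``datasets`` maps modality ->
    ``(CountMatrix, cell_table, gene_table)``.
    """
    if not params:
        raise ValidationError("empty gene program set")
    if n_cells_per_modality < 2:
        raise ValidationError("need at least 2 cells per modality")
    rng = np.random.default_rng(seed)
    gene_ids = [p.gene_id for p in params]
    thetas = np.array([p.theta for p in params])

    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": [p.chromosome for p in params],
            "true_class": [p.true_class for p in params],
            "transcription_off_time": [p.transcription_off_time() for p in params],
        }
    )

    datasets = {}
    truth_cells = {}
    for modality, depth_fn, pool in (
        ("nuclear", nuclear_depth, "n"),
        ("whole_cell", whole_cell_depth, "nc"),
    ):
        t = np.sort(rng.uniform(0.0, 1.0, size=n_cells_per_modality))
        size_factors = rng.lognormal(0.0, 0.25, size=n_cells_per_modality)
        abundance = np.zeros((len(params), n_cells_per_modality))
        for i, p in enumerate(params):
            n_ab, c_ab = kinetic_abundance(p, t)
            abundance[i] = n_ab if pool == "n" else n_ab + c_ab
        counts = _sample_counts(abundance, depth_fn(t), size_factors, thetas, rng)
        prefix = "sn" if modality == "nuclear" else "sc"
        cell_ids = [f"{prefix}_{i:05d}" for i in range(n_cells_per_modality)]
        cm = CountMatrix(counts, gene_ids, cell_ids, modality)
        cell_extra = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "cluster_label": _stage_labels(t),
                "annotation": _stage_labels(t),
                "latent_time": t,
            }
        )
        datasets[modality] = (
            cm,
            make_cell_table(cm, cell_extra),
            make_gene_table(cm, gene_truth),
        )
        truth_cells[modality] = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "latent_time": t,
                "stage": _stage_labels(t),
                "size_factor": size_factors,
            }
        )
    return datasets, SimTruth(cells=truth_cells, genes=gene_truth)


TRUE_TO_INFERRED = {
    "early_program": "early_program",
    "spermatocyte_transient": "coordinate_decay",
    "spermatocyte_perdurant_degraded": "perdurant_degraded_late",
    "spermatocyte_perdurant_stable": "perdurant_stable",
    "spermatid_transcribed": "spermatid_transcribed",
    "flat": "flat",
}
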