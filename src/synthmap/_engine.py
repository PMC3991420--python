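"""Sampling internals for the synthesis-and-mapping models.

The model is linear-Gaussian in the per-contrast reference-scale effects
δ given the mapping coefficients, so δ is marginalized analytically and the
ensemble sampler only explores the hyperparameters (μ1, σ1, mapping
magnitudes, and — for the random-mapping model — the CV φ plus non-centered
per-trial mapping perturbations η). δ and the trial-level mappings are then
recovered draw-by-draw from their exact Gaussian conditionals, which keeps
the funnel geometry out of the sampler entirely.

Parameter vector layout (batch axis first):

    fixed:  [mu1, sigma1, b_2..b_M]
    random: [mu1, sigma1, b_2..b_M, phi, eta_1..eta_L]

where ``b_m > 0`` are mapping magnitudes (signs are fixed a priori) and the
η are standard-normal perturbations, one per (trial, reported non-reference
instrument) pair: the trial-level mapping is β_{j,m} = β_m(1 + φ·η_{jm}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import LikelihoodBlock
from .trial_data import ValidationError

__all__ = ["Design", "build_design", "log_posterior", "run_ensembles",
           "conditional_draws", "initial_positions"]


@dataclass
class _BlockArrays:
    trial_id: str
    ii: np.ndarray          # canonical instrument index per cell
    cc: np.ndarray          # local contrast index per cell
    nc: int                 # number of contrasts
    Cd: np.ndarray          # (nc, nc) between-contrast prior correlation
    S: np.ndarray
    Sinv: np.ndarray
    lat: np.ndarray         # unique non-reference instrument indices present
    lat_col: dict[int, int] = field(default_factory=dict)


@dataclass
class Design:
    instrument_ids: list[str]
    reference: str
    signs: np.ndarray            # ±1 per instrument, +1 at the reference
    blocks: list[_BlockArrays]
    raw_blocks: list[LikelihoodBlock]
    n_lat: int
    lat_offsets: np.ndarray
    n_contrasts: int
    contrast_index: list[tuple[str, str]]   # (trial_id, contrast_id), global order

    @property
    def m(self) -> int:
        return len(self.instrument_ids)

    def ndim(self, random: bool) -> int:
        base = 2 + (self.m - 1)
        return base + 1 + self.n_lat if random else base


def build_design(
    blocks: list[LikelihoodBlock],
    signs: dict[str, int],
    reference: str,
) -> Design:
    if reference not in signs or signs[reference] != 1:
        raise ValidationError(
            f"signs must include the reference instrument {reference!r} with +1"
        )
    order = [reference] + [k for k in signs if k != reference]
    present: set[str] = set()
    for b in blocks:
        present |= {iid for _, iid in b.cells}
    missing = present - set(order)
    if missing:
        raise ValidationError(f"signs missing for instruments: {sorted(missing)}")
    idx = {iid: i for i, iid in enumerate(order)}

    barr: list[_BlockArrays] = []
    contrast_index: list[tuple[str, str]] = []
    lat_offsets = [0]
    for b in blocks:
        ii = np.array([idx[iid] for _, iid in b.cells])
        cpos = {c: i for i, c in enumerate(b.contrast_ids)}
        cc = np.array([cpos[c] for c, _ in b.cells])
        nc = b.n_contrasts
        Cd = np.full((nc, nc), 0.5)
        np.fill_diagonal(Cd, 1.0)
        lat = np.array(sorted({i for i in ii if i != 0}), dtype=int)
        ba = _BlockArrays(
            trial_id=b.trial_id, ii=ii, cc=cc, nc=nc, Cd=Cd,
            S=b.S, Sinv=np.linalg.inv(b.S), lat=lat,
            lat_col={m: q for q, m in enumerate(lat)},
        )
        barr.append(ba)
        contrast_index.extend((b.trial_id, c) for c in b.contrast_ids)
        lat_offsets.append(lat_offsets[-1] + len(lat))

    sign_vec = np.array([signs[iid] for iid in order], dtype=float)
    return Design(
        instrument_ids=order,
        reference=reference,
        signs=sign_vec,
        blocks=barr,
        raw_blocks=list(blocks),
        n_lat=lat_offsets[-1],
        lat_offsets=np.array(lat_offsets),
        n_contrasts=sum(b.nc for b in barr),
        contrast_index=contrast_index,
    )


def _unpack(theta: np.ndarray, design: Design, random: bool):
    m = design.m
    mu = theta[:, 0]
    sig = theta[:, 1]
    b = theta[:, 2 : 1 + m]
    phi = theta[:, 1 + m] if random else None
    eta = theta[:, 2 + m : 2 + m + design.n_lat] if random else None
    return mu, sig, b, phi, eta


def _cell_coefficients(design: Design, beta, phi, eta, j: int):
    """Per-cell mapping coefficient β_{j,m} for block j, batched."""
    blk = design.blocks[j]
    Bj = beta[:, blk.ii].copy()
    if phi is not None:
        lo = design.lat_offsets[j]
        e = eta[:, lo : design.lat_offsets[j + 1]]
        for a, m in enumerate(blk.ii):
            if m != 0:
                Bj[:, a] *= 1.0 + phi * e[:, blk.lat_col[m]]
    return Bj


def log_posterior(theta, design: Design, priors, random: bool):
    """Vectorized log posterior for a (W, ndim) batch of parameter vectors."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    w = theta.shape[0]
    mu, sig, b, phi, eta = _unpack(theta, design, random)

    bad = (sig <= 0) | (sig >= priors.sigma1_upper) | (b <= 0).any(axis=1)
    if random:
        bad |= (phi <= 0) | (phi >= priors.phi_upper)
    sig_safe = np.where(bad, 1.0, sig)

    lp = -(mu**2) / (2 * priors.mu1_sd**2) - (b**2).sum(1) / (2 * priors.beta_sd**2)
    if random:
        lp = lp - (eta**2).sum(1) / 2.0

    beta = np.concatenate([np.ones((w, 1)), design.signs[1:] * b], axis=1)
    ll = np.zeros(w)
    for j, blk in enumerate(design.blocks):
        Bj = _cell_coefficients(design, beta, phi, eta, j)
        d = len(blk.ii)
        A = np.zeros((w, d, blk.nc))
        A[:, np.arange(d), blk.cc] = Bj
        cov = blk.S[None] + sig_safe[:, None, None] ** 2 * np.einsum(
            "wac,cd,wbd->wab", A, blk.Cd, A
        )
        resid = blk_dhat(design, j)[None, :] - mu[:, None] * Bj
        chol = np.linalg.cholesky(cov)
        x = np.linalg.solve(chol, resid[:, :, None])[:, :, 0]
        logdet = 2.0 * np.log(np.einsum("waa->wa", chol)).sum(1)
        ll += -0.5 * ((x**2).sum(1) + logdet)
    return np.where(bad, -np.inf, lp + ll)


def blk_dhat(design: Design, j: int) -> np.ndarray:
    return design.raw_blocks[j].dhat


def _ratio_estimates(design: Design) -> np.ndarray:
    """Crude mapping magnitudes from co-reported effect ratios (init only)."""
    m = design.m
    # accumulate log|ratio| estimates on co-reporting edges, then BFS
    sums = np.zeros((m, m))
    counts = np.zeros((m, m))
    for j, blk in enumerate(design.blocks):
        d = blk_dhat(design, j)
        for a in range(len(blk.ii)):
            for c in range(len(blk.ii)):
                if a == c or blk.cc[a] != blk.cc[c]:
                    continue
                ia, ic = blk.ii[a], blk.ii[c]
                if ia == ic or d[a] == 0 or d[c] == 0:
                    continue
                sums[ia, ic] += np.log(abs(d[c] / d[a]))
                counts[ia, ic] += 1
    logb = np.full(m, np.nan)
    logb[0] = 0.0
    frontier = [0]
    while frontier:
        nxt = []
        for a in frontier:
            for c in range(m):
                if np.isnan(logb[c]) and counts[a, c] > 0:
                    logb[c] = logb[a] + sums[a, c] / counts[a, c]
                    nxt.append(c)
        frontier = nxt
    logb[np.isnan(logb)] = 0.0
    return np.exp(np.clip(logb, -5, 5))


def initial_positions(
    design: Design, priors, nwalkers: int, rng: np.random.Generator, random: bool
) -> np.ndarray:
    b0 = _ratio_estimates(design)
    beta0 = design.signs * b0
    deltas = []
    for j, blk in enumerate(design.blocks):
        d = blk_dhat(design, j)
        for c in range(blk.nc):
            mask = blk.cc == c
            deltas.append(np.mean(d[mask] / beta0[blk.ii[mask]]))
    deltas = np.array(deltas)
    mu0 = float(np.mean(deltas))
    sig0 = float(np.std(deltas) + 0.05 * (abs(mu0) + 1.0))
    sig0 = min(sig0, 0.5 * priors.sigma1_upper)

    ndim = design.ndim(random)
    p0 = np.empty((nwalkers, ndim))
    p0[:, 0] = mu0 + 0.3 * sig0 * rng.standard_normal(nwalkers)
    p0[:, 1] = np.clip(
        sig0 * rng.uniform(0.3, 1.5, nwalkers), 1e-4 * priors.sigma1_upper,
        0.95 * priors.sigma1_upper,
    )
    mags = b0[1:][None, :] * np.abs(1 + 0.2 * rng.standard_normal((nwalkers, design.m - 1)))
    p0[:, 2 : 1 + design.m] = np.clip(mags, 1e-3, None)
    if random:
        p0[:, 1 + design.m] = priors.phi_upper * rng.uniform(0.05, 0.5, nwalkers)
        p0[:, 2 + design.m :] = rng.standard_normal((nwalkers, design.n_lat))
    return p0


def run_ensembles(design: Design, priors, settings, random: bool, seed: int):
    """Run ``settings.chains`` independent stretch-move ensembles.

    Returns (chains, diagnostics): ``chains`` has shape
    (n_chains, n_kept, ndim) with each chain the time-major flattening of
    one ensemble's kept, thinned draws; ``diagnostics`` carries integrated
    autocorrelation times, acceptance fractions and ESS estimates.
    """
    import emcee

    ndim = design.ndim(random)
    nw = settings.walkers or max(2 * ndim + 2, 128 if random else 64)
    steps = settings.steps
    burn = settings.burn if settings.burn is not None else steps // 2
    thin = settings.thin
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(settings.chains)

    chains = []
    taus = []
    accs = []
    for k in range(settings.chains):
        rng = np.random.default_rng(children[k])
        p0 = initial_positions(design, priors, nw, rng, random)
        sampler = emcee.EnsembleSampler(
            nw, ndim,
            log_posterior, args=(design, priors, random),
            vectorize=True,
            moves=emcee.moves.StretchMove(a=settings.stretch_scale),
        )
        sampler.random_state = np.random.RandomState(
            int(children[k].generate_state(1)[0] % (2**31 - 1))
        ).get_state()
        sampler.run_mcmc(p0, steps, progress=False)
        kept = sampler.get_chain(discard=burn, thin=thin)  # (nk, nw, ndim)
        chains.append(kept.reshape(-1, ndim))
        with np.errstate(all="ignore"):
            tau = sampler.get_autocorr_time(discard=burn, tol=0)
        taus.append(tau)
        accs.append(float(sampler.acceptance_fraction.mean()))

    chains = np.array(chains)          # (C, N, ndim)
    tau = np.array(taus).mean(axis=0)  # in steps, pre-thin
    n_eff = settings.chains * nw * (steps - burn) / np.maximum(tau, 1.0)
    diag = {
        "tau": tau,
        "ess": n_eff,
        "acceptance": accs,
        "walkers": nw,
        "steps": steps,
        "burn": burn,
        "thin": thin,
    }
    return chains, diag


def conditional_draws(
    design: Design, theta_flat: np.ndarray, random: bool, rng: np.random.Generator
):
    """Exact Gaussian conditional draws of the per-contrast effects δ, plus
    per-cell predicted effects and full trial-level mapping matrices.

    Returns ``(delta, preds, betaj)`` with ``delta`` of shape (N, total
    contrasts), ``preds`` a list of (N, d_j) arrays in block cell order and
    ``betaj`` of shape (N, n_trials, M) — trial-level mapping coefficients
    for *all* instruments (unreported ones drawn from their prior in the
    random-mapping model).
    """
    n = theta_flat.shape[0]
    mu, sig, b, phi, eta = _unpack(theta_flat, design, random)
    beta = np.concatenate([np.ones((n, 1)), design.signs[1:] * b], axis=1)
    sig2 = np.maximum(sig, 1e-12) ** 2

    delta = np.empty((n, design.n_contrasts))
    preds = []
    betaj = np.empty((n, len(design.blocks), design.m))
    pos = 0
    for j, blk in enumerate(design.blocks):
        Bj = _cell_coefficients(design, beta, phi, eta, j)
        d = len(blk.ii)
        A = np.zeros((n, d, blk.nc))
        A[:, np.arange(d), blk.cc] = Bj
        cinv = np.linalg.inv(blk.Cd)
        prec = np.einsum("wac,ab,wbe->wce", A, blk.Sinv, A) + cinv[None] / sig2[:, None, None]
        rhs = np.einsum("wac,ab,b->wc", A, blk.Sinv, blk_dhat(design, j))
        rhs += cinv.sum(axis=1)[None, :] * (mu / sig2)[:, None]
        cov = np.linalg.inv(prec)
        mean = np.einsum("wce,we->wc", cov, rhs)
        chol = np.linalg.cholesky(cov)
        dj = mean + np.einsum("wce,we->wc", chol, rng.standard_normal((n, blk.nc)))
        delta[:, pos : pos + blk.nc] = dj
        preds.append(np.einsum("wac,wc->wa", A, dj))
        pos += blk.nc

        bj = np.broadcast_to(beta, (n, design.m)).copy()
        if random:
            fac = np.ones((n, design.m))
            lo = design.lat_offsets[j]
            e = eta[:, lo : design.lat_offsets[j + 1]]
            for m in range(1, design.m):
                if m in blk.lat_col:
                    fac[:, m] = 1.0 + phi * e[:, blk.lat_col[m]]
                else:
                    fac[:, m] = 1.0 + phi * rng.standard_normal(n)
            bj = bj * fac
        betaj[:, j, :] = bj
    return delta, preds, betaj
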