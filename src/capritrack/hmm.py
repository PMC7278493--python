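"""Supervised 3-state hidden Markov model with Gaussian-mixture emissions.

The model decodes an animal's behavioral state sequence from per-frame
observation vectors z_k = (x, y, L).  Both parts of the model are estimated
*supervised*, from observer-labeled training tracks:

* the 3×3 transition matrix T (and initial distribution π) by counting
  labeled state transitions, pooled over training animals;
* one emission density p(z | s) per state, a diagonal-covariance Gaussian
  mixture fitted by EM to the frames labeled with that state, with the
  component count chosen by AIC.

Decoding is per-frame marginal MAP: forward filtering gives p(s_k | Z_k),
a Rauch-style backward pass turns it into the smoothed posterior
p(s_k | Z_K), and each frame is assigned its posterior mode.  There is no
Baum–Welch re-estimation and no Viterbi joint decoding here — the procedure
is deliberately the supervised, marginal-smoothing one.

All recursions run in log space with per-step normalization.  A brute-force
path-enumeration oracle (`brute_force_posterior`) provides an independent
check of the recursions on short sequences.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .io import ObservationSequence, Trajectory, assemble_observations, stack_observations

N_STATES = 3
TRANSITION_FLOOR = 1e-10
VARIANCE_FLOOR = 1e-6
DEFAULT_GMM_GRID = tuple(range(1, 16))


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class TransitionMatrix:
    """Markov transition matrix T (rows: from-state) plus initial law π."""

    T: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.T.shape != (N_STATES, N_STATES):
            raise ValueError("T must be 3x3")
        if self.pi.shape != (N_STATES,):
            raise ValueError("pi must have length 3")
        if (self.T < 0).any() or (self.pi < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of T must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-12):
            raise ValueError("pi must sum to 1")

    def stationary(self) -> np.ndarray:
        """Stationary distribution: leading left eigenvector of T."""
        w, v = np.linalg.eig(self.T.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(v[:, i])
        p = np.abs(p)
        return p / p.sum()


@dataclass
class GMMEmission:
    """Diagonal-covariance Gaussian mixture for one state's p(z | s)."""

    state: int
    m: int
    weights: np.ndarray
    means: np.ndarray      # (m, 3)
    variances: np.ndarray  # (m, 3), diagonal entries
    loglik: float
    aic: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-12):
            raise ValueError("mixture weights must sum to 1")
        if (self.variances < VARIANCE_FLOOR * (1 - 1e-12)).any():
            raise ValueError("variance below floor")

    def logpdf(self, z: np.ndarray) -> np.ndarray:
        """Log mixture density at each row of z (accepts (3,) or (K, 3))."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if not np.isfinite(z).all():
            raise ValueError("non-finite observation")
        # (K, m): per-component diagonal Gaussian log-densities
        diff = z[:, None, :] - self.means[None, :, :]
        comp = -0.5 * (
            (diff**2 / self.variances[None, :, :]).sum(axis=2)
            + np.log(2 * np.pi * self.variances).sum(axis=1)[None, :]
        )
        out = logsumexp(comp + np.log(self.weights)[None, :], axis=1)
        return out if out.size > 1 else out.reshape(())


def gmm_n_parameters(m: int, dim: int = 3) -> int:
    """Free parameters of a diagonal m-component mixture: m·2·dim + (m−1)."""
    return m * 2 * dim + (m - 1)


@dataclass
class HMMModel:
    """Complete supervised HMM: transition law plus one emission per state."""

    transition: TransitionMatrix
    emissions: tuple[GMMEmission, GMMEmission, GMMEmission]

    def __post_init__(self) -> None:
        if len(self.emissions) != N_STATES:
            raise ValueError("need exactly one emission model per state")
        states = sorted(e.state for e in self.emissions)
        if states != list(range(N_STATES)):
            raise ValueError("emissions must cover states 0, 1, 2 exactly once")
        self.emissions = tuple(sorted(self.emissions, key=lambda e: e.state))

    def emission_logdensities(self, Z: ObservationSequence | np.ndarray) -> np.ndarray:
        """(K, 3) matrix of log p(z_k | s) for every frame and state."""
        z = Z.z if isinstance(Z, ObservationSequence) else np.atleast_2d(Z)
        return np.column_stack([np.atleast_1d(e.logpdf(z)) for e in self.emissions])


def emission_logdensity(model: HMMModel, z: np.ndarray, state: int) -> float:
    """Log p(z | s=state) under the model's mixture for that state."""
    return float(model.emissions[state].logpdf(np.asarray(z)))


@dataclass
class PosteriorMatrix:
    """Per-frame state posteriors: row k is p(s_k | evidence).

    ``kind`` records the conditioning: "filtered" rows condition on Z_k
    (evidence up to k), "smoothed" rows on the whole sequence Z_K.  Filtered
    matrices additionally carry the one-step predictive p(s_k | Z_{k−1})
    (row 1 holds π) and the total data log-likelihood.
    """

    probs: np.ndarray
    kind: str
    predicted: np.ndarray | None = field(default=None, repr=False)
    loglik: float | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != N_STATES:
            raise ValueError("posterior must have shape (K, 3)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")

    def __len__(self) -> int:
        return len(self.probs)


# ---------------------------------------------------------------------------
# supervised estimation


def estimate_transition_matrix(
    labeled_seqs: Iterable[Sequence[int]],
) -> TransitionMatrix:
    """Count-based transition estimate pooled over labeled sequences.

    p_ij = count(i→j) / count(i→·).  A state never left (zero outgoing
    counts) gets a uniform row; individual zero cells are floored at 1e-10
    and the row renormalized, so log-transition terms stay finite.  π is the
    empirical distribution of first-frame labels.
    """
    counts = np.zeros((N_STATES, N_STATES))
    first = np.zeros(N_STATES)
    n_seqs = 0
    for seq in labeled_seqs:
        s = np.asarray(seq, dtype=int)
        if not np.isin(s, range(N_STATES)).all():
            raise ValueError("labels must lie in {0, 1, 2}")
        if len(s) < 2:
            continue
        n_seqs += 1
        first[s[0]] += 1
        np.add.at(counts, (s[:-1], s[1:]), 1)
    if n_seqs == 0:
        raise ValueError("need at least one label sequence of length >= 2")
    row_tot = counts.sum(axis=1, keepdims=True)
    T = np.where(row_tot > 0, counts / np.where(row_tot > 0, row_tot, 1), 1.0 / N_STATES)
    T = np.maximum(T, TRANSITION_FLOOR)
    T /= T.sum(axis=1, keepdims=True)
    return TransitionMatrix(T=T, pi=first / first.sum())


def fit_state_gmm(obs: np.ndarray, m: int, seed: int = 0) -> GMMEmission:
    """EM-fit a diagonal m-component mixture to one state's observations.

    Initialization is seeded k-means; variances are floored at 1e-6
    (squared length-units) so the density stays finite even on degenerate
    coordinates.  AIC = −2·loglik + 2·(7m−1).
    """
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observations must have shape (n, 3)")
    if m < 1:
        raise ValueError("component count must be >= 1")
    if len(obs) < m:
        raise ValueError(f"cannot fit {m} components to {len(obs)} observations")
    state = -1  # caller may overwrite; fit is state-agnostic
    gm = GaussianMixture(
        n_components=m,
        covariance_type="diag",
        reg_covar=VARIANCE_FLOOR,
        max_iter=200,
        tol=1e-8,
        n_init=1,
        init_params="kmeans",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence reported via flag
        gm.fit(obs)
    loglik = float(gm.score(obs) * len(obs))
    aic = -2.0 * loglik + 2.0 * gmm_n_parameters(m)
    if not gm.converged_:
        warnings.warn(f"EM did not converge for m={m}; returning best iterate")
    return GMMEmission(
        state=state,
        m=m,
        weights=gm.weights_ / gm.weights_.sum(),
        means=gm.means_,
        variances=np.maximum(gm.covariances_, VARIANCE_FLOOR),
        loglik=loglik,
        aic=aic,
        converged=bool(gm.converged_),
    )


def select_gmm_components_aic(
    obs: np.ndarray,
    m_grid: Sequence[int] = DEFAULT_GMM_GRID,
    seed: int = 0,
) -> GMMEmission:
    """Fit the mixture at every grid size and keep the minimum-AIC fit.

    Ties go to the smaller component count.  Grid entries infeasible for the
    sample size are skipped with a warning; if all are, this is an error.
    """
    if len(m_grid) == 0:
        raise ValueError("empty component grid")
    best: GMMEmission | None = None
    for m in sorted(m_grid):
        if m > len(obs):
            warnings.warn(f"skipping m={m}: only {len(obs)} observations")
            continue
        fit = fit_state_gmm(obs, m, seed=seed)
        if best is None or fit.aic < best.aic:
            best = fit
    if best is None:
        raise ValueError("no feasible component count in grid")
    return best


# ---------------------------------------------------------------------------
# recursions


def forward_filter(model: HMMModel, Z: ObservationSequence | np.ndarray) -> PosteriorMatrix:
    """Forward pass: filtered posteriors p(s_k | Z_k).

    Alternates the one-step prediction p(s_k | Z_{k−1}) = Tᵀ p(s_{k−1} | Z_{k−1})
    with the Bayes update against the emission density, normalizing every
    step; the normalizers accumulate into log p(Z_K).
    """
    logb = model.emission_logdensities(Z)
    K = len(logb)
    if K < 1:
        raise ValueError("empty observation sequence")
    T = model.transition.T
    filtered = np.empty((K, N_STATES))
    predicted = np.empty((K, N_STATES))
    loglik = 0.0
    with np.errstate(divide="ignore"):
        pred = model.transition.pi.copy()
        for k in range(K):
            predicted[k] = pred
            log_unnorm = np.log(pred) + logb[k]
            c = logsumexp(log_unnorm)
            if not np.isfinite(c):
                raise FloatingPointError(f"zero total likelihood at frame {k + 1}")
            loglik += c
            filtered[k] = np.exp(log_unnorm - c)
            pred = T.T @ filtered[k]
    return PosteriorMatrix(probs=filtered, kind="filtered", predicted=predicted, loglik=loglik)


def backward_smooth(model: HMMModel, filtered: PosteriorMatrix) -> PosteriorMatrix:
    """Backward pass: smoothed posteriors p(s_k | Z_K).

    Rauch-style recursion
        p(s_k|Z_K) = p(s_k|Z_k) Σ_{s_{k+1}} p(s_{k+1}|Z_K) p(s_{k+1}|s_k) / p(s_{k+1}|Z_k);
    the last row equals the filtered one.  Ratio terms with zero predictive
    probability contribute zero (their smoothed numerator is then zero too).
    """
    if filtered.kind != "filtered" or filtered.predicted is None:
        raise ValueError("backward_smooth needs the output of forward_filter")
    f = filtered.probs
    K = len(f)
    T = model.transition.T
    smoothed = np.empty_like(f)
    smoothed[-1] = f[-1]
    for k in range(K - 2, -1, -1):
        pred_next = filtered.predicted[k + 1]
        ratio = np.divide(
            smoothed[k + 1], pred_next,
            out=np.zeros(N_STATES), where=pred_next > 0,
        )
        smoothed[k] = f[k] * (T @ ratio)
        smoothed[k] /= smoothed[k].sum()
    return PosteriorMatrix(probs=smoothed, kind="smoothed", loglik=filtered.loglik)


def decode_map(smoothed: PosteriorMatrix) -> np.ndarray:
    """Per-frame MAP state: argmax of each posterior row (ties → smallest id)."""
    return np.argmax(smoothed.probs, axis=1)


def smooth(model: HMMModel, Z: ObservationSequence | np.ndarray) -> PosteriorMatrix:
    """Convenience: forward filter then backward smooth."""
    return backward_smooth(model, forward_filter(model, Z))


def brute_force_posterior(
    model: HMMModel, Z: ObservationSequence | np.ndarray
) -> PosteriorMatrix:
    """Exact smoothed marginals by enumerating all 3^K state paths.

    Test oracle only — refuses K > 10.
    """
    logb = model.emission_logdensities(Z)
    K = len(logb)
    if K > 10:
        raise ValueError("path enumeration limited to K <= 10")
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.transition.pi)
        log_T = np.log(model.transition.T)
    marg = np.full((K, N_STATES), -np.inf)
    for path in itertools.product(range(N_STATES), repeat=K):
        lp = log_pi[path[0]] + logb[0, path[0]]
        for k in range(1, K):
            lp += log_T[path[k - 1], path[k]] + logb[k, path[k]]
        for k, s in enumerate(path):
            marg[k, s] = np.logaddexp(marg[k, s], lp)
    marg -= logsumexp(marg, axis=1, keepdims=True)
    return PosteriorMatrix(probs=np.exp(marg), kind="smoothed")


# ---------------------------------------------------------------------------
# serialization

def model_to_dict(model: HMMModel) -> dict:
    return {
        "transition": {
            "T": model.transition.T.tolist(),
            "pi": model.transition.pi.tolist(),
        },
        "emissions": [
            {
                "state": e.state,
                "m": e.m,
                "weights": e.weights.tolist(),
                "means": e.means.tolist(),
                "variances": e.variances.tolist(),
                "loglik": e.loglik,
                "aic": e.aic,
                "converged": e.converged,
            }
            for e in model.emissions
        ],
    }


def model_from_dict(d: dict) -> HMMModel:
    tr = TransitionMatrix(T=np.array(d["transition"]["T"]), pi=np.array(d["transition"]["pi"]))
    ems = tuple(
        GMMEmission(
            state=e["state"],
            m=e["m"],
            weights=np.array(e["weights"]),
            means=np.array(e["means"]),
            variances=np.array(e["variances"]),
            loglik=e["loglik"],
            aic=e["aic"],
            converged=e.get("converged", True),
        )
        for e in d["emissions"]
    )
    return HMMModel(transition=tr, emissions=ems)


def save_model(model: HMMModel, path: str | Path) -> None:
    """JSON round-trip preserves every float bit-exactly (repr-based)."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> HMMModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# modelling-object API


class EstrusBehaviorHMM:
    """Supervised behavioral-state HMM, built from labeled training tracks.

    Parameters
    ----------
    trajectories : sequence of Trajectory
        Labeled training animals.  Transition counts are pooled over all of
        them; emission mixtures are fitted per state to the pooled frames.
    gmm_grid : sequence of int
        Candidate mixture sizes per state; AIC picks one.
    seed : int
        Seed for the EM initializations.

    Examples
    --------
    >>> model = EstrusBehaviorHMM(train_trajs, seed=0)
    >>> res = model.fit()
    >>> states = res.decode(test_traj)
    """

    def __init__(
        self,
        trajectories: Sequence[Trajectory],
        gmm_grid: Sequence[int] = DEFAULT_GMM_GRID,
        seed: int = 0,
    ) -> None:
        if not trajectories:
            raise ValueError("need at least one training trajectory")
        for t in trajectories:
            if not t.is_labeled:
                raise ValueError(f"training trajectory {t.animal_id!r} is unlabeled")
        self.trajectories = list(trajectories)
        self.gmm_grid = tuple(gmm_grid)
        self.seed = int(seed)
        self.features, self.labels = stack_observations(self.trajectories)

    def fit(self) -> "HMMResults":
        transition = estimate_transition_matrix([t.labels for t in self.trajectories])
        emissions = []
        for s in range(N_STATES):
            obs_s = self.features[self.labels == s]
            if len(obs_s) == 0:
                raise ValueError(f"no training frames labeled state {s}")
            em = select_gmm_components_aic(obs_s, self.gmm_grid, seed=self.seed)
            em.state = s
            emissions.append(em)
        return HMMResults(self, HMMModel(transition=transition, emissions=tuple(emissions)))


class HMMResults:
    """Fitted supervised HMM: parameter estimates plus decoding methods."""

    def __init__(self, model: EstrusBehaviorHMM | None, params: HMMModel) -> None:
        self.model = model
        self.params = params

    # -- convenience views -------------------------------------------------
    @property
    def transition(self) -> TransitionMatrix:
        return self.params.transition

    @property
    def emissions(self) -> tuple[GMMEmission, ...]:
        return self.params.emissions

    # -- inference ---------------------------------------------------------
    def _observations(self, data) -> ObservationSequence:
        if isinstance(data, Trajectory):
            return assemble_observations(data)
        if isinstance(data, ObservationSequence):
            return data
        return ObservationSequence(np.asarray(data, dtype=float))

    def filtered(self, data) -> PosteriorMatrix:
        return forward_filter(self.params, self._observations(data))

    def smoothed(self, data) -> PosteriorMatrix:
        return smooth(self.params, self._observations(data))

    def decode(self, data) -> np.ndarray:
        """MAP state sequence from the smoothed marginals."""
        return decode_map(self.smoothed(data))

    def loglikelihood(self, data) -> float:
        return float(self.filtered(data).loglik)

    # -- persistence / reporting -------------------------------------------
    def save(self, path: str | Path) -> None:
        save_model(self.params, path)

    @classmethod
    def from_file(cls, path: str | Path) -> "HMMResults":
        return cls(None, load_model(path))

    def summary(self) -> str:
        from .io import STATE_NAMES

        tr = self.params.transition
        lines = ["Supervised estrus-behavior HMM", "=" * 34]
        if self.model is not None:
            lines.append(
                f"Training: {len(self.model.trajectories)} animals, "
                f"{len(self.model.features)} frames"
            )
        lines.append("Transition matrix (rows: from-state):")
        for i in range(N_STATES):
            cells = "  ".join(f"{tr.T[i, j]:.4f}" for j in range(N_STATES))
            lines.append(f"  {STATE_NAMES[i]:<12} {cells}")
        pi = "  ".join(f"{p:.4f}" for p in tr.pi)
        lines.append(f"Initial distribution: {pi}")
        lines.append("Emission mixtures (AIC-selected):")
        for e in self.params.emissions:
            lines.append(
                f"  state {e.state} ({STATE_NAMES[e.state]}): m={e.m}, "
                f"loglik={e.loglik:.1f}, AIC={e.aic:.1f}"
            )
        return "\n".join(lines)

    def plot_posterior(self, data, ax=None):
        """Plot smoothed state posteriors over frames (matplotlib axes)."""
        import matplotlib.pyplot as plt

        from .io import STATE_NAMES

        post = self.smoothed(data)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        k = np.arange(1, len(post) + 1)
        for s in range(N_STATES):
            ax.plot(k, post.probs[:, s], label=STATE_NAMES[s])
        ax.set_xlabel("frame")
        ax.set_ylabel("p(state | all frames)")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(loc="upper right", fontsize="small")
        return ax
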