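"""Synthetic goat-cohort generator.

No tracking data accompanied the study this pipeline reimplements, so the
generator produces cohorts with the same *structure*: 16 animals (8 estrus,
8 non-estrus), 1200 frames each (10 min at one frame per 0.5 s), three
observer-labeled behavioral states, in a square pen whose small-x side is
adjacent to the male paddock.

States evolve by a Markov chain; positions follow a state-attracted
correlated walk — each frame the animal relaxes a fraction of the way toward
the anchor point of its current state's position kernel and takes Gaussian
displacement noise scaled by the state's movement speed.  That makes all
three observables informative: an estrus animal *approaching* takes large
steps toward small x, *standing* takes tiny steps hard against the male
side, and state 0 wanders mid-pen.  An alternative "gaussian" mode draws
positions i.i.d. from the state's kernel instead, matching the decoder's own
emission assumptions exactly — useful for oracle-sharp recovery tests.

Labels equal the generating states, optionally flipped uniformly at a
configurable label-noise rate (imitating observer error).  Everything is
reproducible from the cohort seed; animal i uses seed ``seed + i``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np

from .hmm import TransitionMatrix
from .io import Trajectory


@dataclass
class StateKernel:
    """One 2-D Gaussian position kernel: mean and diagonal sd, pen units."""

    mean: tuple[float, float]
    sd: tuple[float, float]
    weight: float = 1.0


@dataclass
class StateSpec:
    """Position kernels plus movement dynamics for one behavioral state."""

    kernels: list[StateKernel]
    speed_sd: float        # per-frame displacement noise, length-units
    attraction: float = 0.3  # fraction of the gap to the anchor closed per frame

    def kernel_weights(self) -> np.ndarray:
        w = np.array([k.weight for k in self.kernels], dtype=float)
        return w / w.sum()


@dataclass
class GroupProfile:
    """Generative recipe for one cohort group: chain plus state kernels."""

    transition: TransitionMatrix
    states: tuple[StateSpec, StateSpec, StateSpec]


@dataclass
class CohortConfig:
    """Full synthetic-cohort recipe (geometry, chains, kernels, counts, seed)."""

    estrus_profile: GroupProfile
    nonestrus_profile: GroupProfile
    pen_width: float = 1.0
    pen_height: float = 1.0
    n_frames: int = 1200
    n_estrus: int = 8
    n_nonestrus: int = 8
    label_noise: float = 0.0
    seed: int = 0
    mode: str = "walk"  # "walk" (correlated) or "gaussian" (i.i.d. positions)

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.n_estrus < 0 or self.n_nonestrus < 0:
            raise ValueError("animal counts must be >= 0")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")
        if self.mode not in ("walk", "gaussian"):
            raise ValueError("mode must be 'walk' or 'gaussian'")


def _estrus_states() -> tuple[StateSpec, StateSpec, StateSpec]:
    # male paddock at x = 0; estrus animals concentrate near it
    return (
        StateSpec([StateKernel((0.70, 0.50), (0.15, 0.20))], speed_sd=0.04),
        StateSpec([StateKernel((0.15, 0.50), (0.10, 0.20))], speed_sd=0.10),
        StateSpec([StateKernel((0.06, 0.50), (0.04, 0.15))], speed_sd=0.01),
    )


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-shaped cohort: 8 estrus animals biased toward states 1/2 at
    small x, 8 non-estrus animals dwelling in state 0 away from the male."""
    estrus_T = TransitionMatrix(
        T=np.array(
            [
                [0.90, 0.07, 0.03],
                [0.04, 0.88, 0.08],
                [0.01, 0.02, 0.97],
            ]
        ),
        pi=np.array([0.50, 0.15, 0.35]),
    )
    nonestrus_T = TransitionMatrix(
        T=np.array(
            [
                [0.975, 0.020, 0.005],
                [0.200, 0.780, 0.020],
                [0.100, 0.050, 0.850],
            ]
        ),
        pi=np.array([0.90, 0.07, 0.03]),
    )
    nonestrus_states = (
        StateSpec([StateKernel((0.75, 0.50), (0.15, 0.22))], speed_sd=0.05),
        StateSpec([StateKernel((0.30, 0.50), (0.12, 0.20))], speed_sd=0.09),
        StateSpec([StateKernel((0.08, 0.50), (0.05, 0.15))], speed_sd=0.01),
    )
    return CohortConfig(
        estrus_profile=GroupProfile(estrus_T, _estrus_states()),
        nonestrus_profile=GroupProfile(nonestrus_T, nonestrus_states),
        seed=seed,
        **overrides,
    )


def recovery_config(seed: int = 0, **overrides) -> CohortConfig:
    """Parameter-recovery cohort: one shared true chain for every animal and
    widely separated position kernels drawn i.i.d. per state, so the pooled
    supervised estimate has a single well-defined truth and decoding is
    near-noiseless."""
    shared_T = TransitionMatrix(
        T=np.array(
            [
                [0.94, 0.04, 0.02],
                [0.03, 0.92, 0.05],
                [0.02, 0.04, 0.94],
            ]
        ),
        pi=np.array([0.4, 0.3, 0.3]),
    )
    states = (
        StateSpec([StateKernel((0.85, 0.15), (0.03, 0.03))], speed_sd=0.03),
        StateSpec([StateKernel((0.50, 0.85), (0.03, 0.03))], speed_sd=0.03),
        StateSpec([StateKernel((0.10, 0.15), (0.03, 0.03))], speed_sd=0.03),
    )
    profile = GroupProfile(shared_T, states)
    overrides.setdefault("mode", "gaussian")
    return CohortConfig(
        estrus_profile=profile,
        nonestrus_profile=profile,
        seed=seed,
        **overrides,
    )


def simulate_states(transition: TransitionMatrix, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a state path from the Markov chain (π, T)."""
    cum_pi = np.cumsum(transition.pi)
    cum_T = np.cumsum(transition.T, axis=1)
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype=int)
    states[0] = np.searchsorted(cum_pi, u[0])
    for k in range(1, n_frames):
        states[k] = np.searchsorted(cum_T[states[k - 1]], u[k])
    return states


def simulate_trajectory(
    profile: GroupProfile,
    n_frames: int,
    seed: int,
    pen: tuple[float, float] = (1.0, 1.0),
    label_noise: float = 0.0,
    mode: str = "walk",
    animal_id: str = "sim",
    estrus: bool = False,
) -> Trajectory:
    """Simulate one labeled track from a group profile.

    Positions are clipped to [0, W] × [0, H].  Labels equal the generating
    states, each then flipped with probability ``label_noise`` to one of the
    other two states, uniformly.
    """
    rng = np.random.default_rng(seed)
    states = simulate_states(profile.transition, n_frames, rng)
    W, H = pen
    pos = np.empty((n_frames, 2))
    if mode == "gaussian":
        for k in range(n_frames):
            spec = profile.states[states[k]]
            ki = rng.choice(len(spec.kernels), p=spec.kernel_weights())
            kern = spec.kernels[ki]
            pos[k] = rng.normal(kern.mean, kern.sd)
    elif mode == "walk":
        spec = profile.states[states[0]]
        ki = rng.choice(len(spec.kernels), p=spec.kernel_weights())
        anchor = np.array(spec.kernels[ki].mean)
        pos[0] = rng.normal(anchor, spec.kernels[ki].sd)
        for k in range(1, n_frames):
            spec = profile.states[states[k]]
            if states[k] != states[k - 1]:
                ki = rng.choice(len(spec.kernels), p=spec.kernel_weights())
                anchor = rng.normal(
                    spec.kernels[ki].mean, spec.kernels[ki].sd
                )  # fresh dwell point inside the kernel
            pos[k] = (
                pos[k - 1]
                + spec.attraction * (anchor - pos[k - 1])
                + rng.normal(0.0, spec.speed_sd, 2)
            )
    else:
        raise ValueError("mode must be 'walk' or 'gaussian'")
    pos[:, 0] = np.clip(pos[:, 0], 0.0, W)
    pos[:, 1] = np.clip(pos[:, 1], 0.0, H)

    labels = states.copy()
    if label_noise > 0:
        flip = rng.random(n_frames) < label_noise
        shift = rng.integers(1, 3, size=n_frames)  # +1 or +2 mod 3 -> other states
        labels[flip] = (labels[flip] + shift[flip]) % 3
    return Trajectory(
        animal_id=animal_id,
        estrus=estrus,
        x=pos[:, 0],
        y=pos[:, 1],
        labels=labels,
        true_states=states,
    )


def simulate_cohort(config: CohortConfig) -> tuple[list[Trajectory], dict]:
    """Simulate the full cohort; returns (trajectories, truth manifest).

    The manifest records the config and each animal's group, id and seed so
    every number downstream is reproducible from it.
    """
    if config.n_estrus + config.n_nonestrus == 0:
        raise ValueError("cohort must contain at least one animal")
    trajs: list[Trajectory] = []
    animals = []
    idx = 0
    for group, profile, count in (
        ("estrus", config.estrus_profile, config.n_estrus),
        ("nonestrus", config.nonestrus_profile, config.n_nonestrus),
    ):
        for j in range(count):
            animal_id = f"{'est' if group == 'estrus' else 'non'}{j + 1:02d}"
            seed = config.seed + idx
            trajs.append(
                simulate_trajectory(
                    profile,
                    config.n_frames,
                    seed=seed,
                    pen=(config.pen_width, config.pen_height),
                    label_noise=config.label_noise,
                    mode=config.mode,
                    animal_id=animal_id,
                    estrus=(group == "estrus"),
                )
            )
            animals.append({"animal_id": animal_id, "group": group, "seed": seed})
            idx += 1
    manifest = {"config": config_to_dict(config), "animals": animals}
    return trajs, manifest


# ---------------------------------------------------------------------------
# config (de)serialization — JSON truth manifest


def config_to_dict(config: CohortConfig) -> dict:
    def profile(p: GroupProfile) -> dict:
        return {
            "transition": {"T": p.transition.T.tolist(), "pi": p.transition.pi.tolist()},
            "states": [
                {
                    "kernels": [asdict(k) for k in s.kernels],
                    "speed_sd": s.speed_sd,
                    "attraction": s.attraction,
                }
                for s in p.states
            ],
        }

    return {
        "estrus_profile": profile(config.estrus_profile),
        "nonestrus_profile": profile(config.nonestrus_profile),
        "pen_width": config.pen_width,
        "pen_height": config.pen_height,
        "n_frames": config.n_frames,
        "n_estrus": config.n_estrus,
        "n_nonestrus": config.n_nonestrus,
        "label_noise": config.label_noise,
        "seed": config.seed,
        "mode": config.mode,
    }


def config_from_dict(d: dict) -> CohortConfig:
    def profile(pd: dict) -> GroupProfile:
        tr = TransitionMatrix(
            T=np.array(pd["transition"]["T"]), pi=np.array(pd["transition"]["pi"])
        )
        states = tuple(
            StateSpec(
                kernels=[
                    StateKernel(tuple(k["mean"]), tuple(k["sd"]), k.get("weight", 1.0))
                    for k in s["kernels"]
                ],
                speed_sd=s["speed_sd"],
                attraction=s.get("attraction", 0.3),
            )
            for s in pd["states"]
        )
        return GroupProfile(tr, states)

    return CohortConfig(
        estrus_profile=profile(d["estrus_profile"]),
        nonestrus_profile=profile(d["nonestrus_profile"]),
        pen_width=d["pen_width"],
        pen_height=d["pen_height"],
        n_frames=d["n_frames"],
        n_estrus=d["n_estrus"],
        n_nonestrus=d["n_nonestrus"],
        label_noise=d["label_noise"],
        seed=d["seed"],
        mode=d["mode"],
    )


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1))


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
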