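"""Tabular Q-learning controller driven by validation loss.

The controller keeps one integer score per bucket. After each validation
it compares the new validation loss against the previous one and emits a
three-valued reward: +1 if the loss fell, -1 if it rose, 0 if unchanged.
The current bucket's score is incremented by the reward, and on a negative
reward the controller advances to the next bucket cyclically; otherwise
the current bucket stays active. At the end of training the bucket with
the highest score is the discovered augmentation policy.

The previous loss starts at 1000, so the first validation always yields a
positive reward. By default an unchanged loss leaves the score untouched;
``increment_on_equal=True`` switches to the variant where equality also
increments the score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

INITIAL_PREV_LOSS = 1000.0


@dataclass(frozen=True)
class ValidationRecord:
    step: int
    loss: float
    reward: int
    bucket: int


@dataclass(frozen=True)
class ControllerState:
    """Immutable controller state; updates return a new state."""

    q: tuple[int, ...]
    current: int
    prev_loss: float
    history: tuple[ValidationRecord, ...]
    n_buckets: int
    increment_on_equal: bool = False

    def __post_init__(self) -> None:
        if len(self.q) != self.n_buckets:
            raise ValueError("Q-table size does not match n_buckets")
        if not 0 <= self.current < self.n_buckets:
            raise ValueError("current bucket index out of range")

    def to_dict(self) -> dict:
        return {
            "q": list(self.q),
            "current": self.current,
            "prev_loss": self.prev_loss,
            "n_buckets": self.n_buckets,
            "increment_on_equal": self.increment_on_equal,
            "history": [
                {"step": r.step, "loss": r.loss, "reward": r.reward,
                 "bucket": r.bucket}
                for r in self.history
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControllerState":
        return cls(
            q=tuple(int(v) for v in d["q"]),
            current=int(d["current"]),
            prev_loss=float(d["prev_loss"]),
            history=tuple(
                ValidationRecord(int(r["step"]), float(r["loss"]),
                                 int(r["reward"]), int(r["bucket"]))
                for r in d["history"]
            ),
            n_buckets=int(d["n_buckets"]),
            increment_on_equal=bool(d.get("increment_on_equal", False)),
        )


def init_controller(n_buckets: int, seed: int,
                    increment_on_equal: bool = False) -> ControllerState:
    """Fresh state: all scores zero, previous loss 1000, random start bucket."""
    if n_buckets < 1:
        raise ValueError(f"n_buckets must be >= 1, got {n_buckets}")
    rng = np.random.default_rng(seed)
    return ControllerState(
        q=(0,) * n_buckets,
        current=int(rng.integers(n_buckets)),
        prev_loss=INITIAL_PREV_LOSS,
        history=(),
        n_buckets=n_buckets,
        increment_on_equal=increment_on_equal,
    )


def observe_validation(state: ControllerState,
                       new_loss: float) -> tuple[ControllerState, int]:
    """Consume one validation loss; return the updated state and the reward.

    reward = -1 if the loss rose (score decremented, controller advances
    cyclically to the next bucket), +1 if it fell (score incremented,
    bucket unchanged), 0 if equal (no change, unless the state was built
    with ``increment_on_equal``).
    """
    new_loss = float(new_loss)
    if not np.isfinite(new_loss):
        raise ValueError(f"validation loss must be finite, got {new_loss}")
    if new_loss < 0:
        raise ValueError(f"validation loss must be non-negative, got {new_loss}")

    if new_loss > state.prev_loss:
        reward = -1
    elif new_loss < state.prev_loss:
        reward = 1
    else:
        reward = 1 if state.increment_on_equal else 0

    q = list(state.q)
    q[state.current] += reward
    current = state.current
    if reward == -1:
        current = (current + 1) % state.n_buckets
    record = ValidationRecord(step=len(state.history), loss=new_loss,
                              reward=reward, bucket=state.current)
    new_state = replace(
        state,
        q=tuple(q),
        current=current,
        prev_loss=new_loss,
        history=state.history + (record,),
    )
    return new_state, reward


def best_bucket(state: ControllerState) -> int:
    """Index with the maximal score; ties broken by the lowest index."""
    return int(np.argmax(state.q))


def run_mock_search(effects: list[float], n_rounds: int,
                    seed: int) -> ControllerState:
    """Simulate the controller against synthetic per-bucket improvement odds.

    ``effects[i]`` is the probability that a validation interval under
    bucket ``i`` lowers the validation loss by a fixed step (with small
    additive noise); otherwise the loss rises by the same step. A test
    harness for convergence: the bucket with the highest improvement
    probability should accumulate the highest score.
    """
    if len(effects) == 0:
        raise ValueError("effects must be non-empty")
    effects = [float(p) for p in effects]
    if any(not 0.0 <= p <= 1.0 for p in effects):
        raise ValueError("every effect probability must be in [0, 1]")
    if n_rounds < 1:
        raise ValueError(f"n_rounds must be >= 1, got {n_rounds}")

    rng = np.random.default_rng(seed)
    state = init_controller(len(effects), seed=int(rng.integers(2**31)))
    loss = 1.0
    step = 1e-3
    for _ in range(n_rounds):
        improves = rng.random() < effects[state.current]
        noise = rng.uniform(-1e-4, 1e-4)
        loss = loss - step + noise if improves else loss + step + noise
        loss = max(loss, 1e-6)
        state, _ = observe_validation(state, loss)
    return state
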