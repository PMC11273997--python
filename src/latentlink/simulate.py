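"""Synthetic item-response data with known factor structure.

Generates continuous indicators from a common-factor measurement model

    x_j = tau_j + f_j(lambda_j, xi) + eps_j,      eps_j ~ N(0, sigma2_j),

where the per-item link ``f_j`` is either linear, ``lambda * xi``, or the
bounded sigmoid ``1 / (1 + exp(-3 * xi * lambda))``.  Factor scores ``xi``
are drawn i.i.d. normal and, in multi-factor designs, independent across
factors with simple structure (each item loads on exactly one factor).

The default one-factor recipe is 8 indicators, all loadings 0.8, intercepts
0, residual variance 0.20 and standard-normal scores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ItemSpec",
    "MeasurementSpec",
    "SimulatedDataset",
    "sigmoid_link",
    "simulate_dataset",
    "benchmark_suite",
    "write_dataset",
    "read_dataset",
    "BENCHMARK_CONDITIONS",
]

LinkName = Literal["linear", "sigmoid"]

#: steepness constant of the sigmoidal link
SIGMOID_GAIN = 3.0


class SpecError(ValueError):
    """Raised when a measurement specification is internally inconsistent."""


def sigmoid_link(loading: float, scores: np.ndarray) -> np.ndarray:
    """Sigmoidal item-factor link ``1 / (1 + exp(-3 * xi * loading))``.

    Strictly bounded in (0, 1) and monotone increasing in ``scores`` for
    positive ``loading``.
    """
    scores = np.asarray(scores, dtype=float)
    return 1.0 / (1.0 + np.exp(-SIGMOID_GAIN * scores * loading))


def linear_link(loading: float, scores: np.ndarray) -> np.ndarray:
    """Linear item-factor link ``loading * xi``."""
    return loading * np.asarray(scores, dtype=float)


_LINKS = {"linear": linear_link, "sigmoid": sigmoid_link}


@dataclass(frozen=True)
class ItemSpec:
    """Generative recipe for a single indicator."""

    link: LinkName = "linear"
    loading: float = 0.8
    intercept: float = 0.0
    residual_variance: float = 0.20
    factor_index: int = 0

    def validate(self, n_factors: int, label: str = "item") -> None:
        if self.link not in _LINKS:
            raise SpecError(f"{label}: unknown link {self.link!r}")
        if self.residual_variance < 0:
            raise SpecError(
                f"{label}: residual_variance must be >= 0, got {self.residual_variance}"
            )
        if not 0 <= self.factor_index < n_factors:
            raise SpecError(
                f"{label}: factor_index {self.factor_index} out of range for "
                f"{n_factors} factor(s)"
            )


@dataclass(frozen=True)
class MeasurementSpec:
    """Full generative recipe: items, factor count and score distribution."""

    n_factors: int = 1
    items: tuple[ItemSpec, ...] = ()
    score_mean: float = 0.0
    score_variance: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def n_items(self) -> int:
        return len(self.items)

    def validate(self) -> None:
        if self.n_factors < 1:
            raise SpecError("n_factors must be >= 1")
        if self.score_variance <= 0:
            raise SpecError("score_variance must be > 0")
        if not self.items:
            raise SpecError("spec has no items")
        for j, item in enumerate(self.items):
            item.validate(self.n_factors, label=f"item_{j + 1}")
        referenced = {it.factor_index for it in self.items}
        missing = set(range(self.n_factors)) - referenced
        if missing:
            raise SpecError(
                "factor(s) with no indicator: "
                + ", ".join(str(f) for f in sorted(missing))
            )

    @property
    def loadings(self) -> np.ndarray:
        """Items x factors loading matrix implied by the spec (simple structure)."""
        lam = np.zeros((self.n_items, self.n_factors))
        for j, it in enumerate(self.items):
            lam[j, it.factor_index] = it.loading
        return lam

    @property
    def link_names(self) -> tuple[str, ...]:
        return tuple(it.link for it in self.items)

    def to_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "items": [asdict(it) for it in self.items],
            "score_mean": self.score_mean,
            "score_variance": self.score_variance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementSpec":
        return cls(
            n_factors=d["n_factors"],
            items=tuple(ItemSpec(**it) for it in d["items"]),
            score_mean=d.get("score_mean", 0.0),
            score_variance=d.get("score_variance", 1.0),
        )


def make_spec(
    n_factors: int = 1,
    n_items_per_factor: int = 8,
    n_sigmoid_per_factor: int = 0,
    loading: float = 0.8,
    intercept: float = 0.0,
    residual_variance: float = 0.20,
) -> MeasurementSpec:
    """Build a simple-structure spec; sigmoidal items are the last of each block."""
    if n_sigmoid_per_factor > n_items_per_factor:
        raise SpecError("n_sigmoid_per_factor exceeds n_items_per_factor")
    items = []
    for f in range(n_factors):
        for j in range(n_items_per_factor):
            link = "sigmoid" if j >= n_items_per_factor - n_sigmoid_per_factor else "linear"
            items.append(
                ItemSpec(
                    link=link,
                    loading=loading,
                    intercept=intercept,
                    residual_variance=residual_variance,
                    factor_index=f,
                )
            )
    return MeasurementSpec(n_factors=n_factors, items=tuple(items))


@dataclass(frozen=True)
class SimulatedDataset:
    """Item responses together with the true scores and spec that produced them."""

    responses: np.ndarray  # (n_subjects, n_items)
    true_scores: np.ndarray  # (n_subjects, n_factors)
    spec: MeasurementSpec
    seed: int
    name: str = ""

    @property
    def n_subjects(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]


def simulate_dataset(
    spec: MeasurementSpec,
    n_subjects: int = 1000,
    seed: int = 0,
    name: str = "",
) -> SimulatedDataset:
    """Draw a sample from the measurement model defined by ``spec``.

    Scores and residuals come from separate child streams of the master seed,
    so changing the item list never perturbs the score draws.  Regenerating
    with the same seed and spec reproduces the responses bit-for-bit.
    """
    spec.validate()
    if n_subjects < 2:
        raise SpecError("n_subjects must be >= 2")
    ss = np.random.SeedSequence([int(seed), 0x1A7E])
    score_rng, resid_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    scores = score_rng.normal(
        spec.score_mean,
        np.sqrt(spec.score_variance),
        size=(n_subjects, spec.n_factors),
    )
    responses = np.empty((n_subjects, spec.n_items))
    for j, item in enumerate(spec.items):
        xi = scores[:, item.factor_index]
        signal = _LINKS[item.link](item.loading, xi)
        eps = resid_rng.normal(0.0, np.sqrt(item.residual_variance), size=n_subjects)
        responses[:, j] = item.intercept + signal + eps
    return SimulatedDataset(
        responses=responses, true_scores=scores, spec=spec, seed=int(seed), name=name
    )


#: the six benchmark conditions: {1, 2 factors} x {0, 1, 4 sigmoid items per factor}
BENCHMARK_CONDITIONS: tuple[tuple[str, int, int], ...] = (
    ("1f_linear", 1, 0),
    ("1f_1sigmoid", 1, 1),
    ("1f_4sigmoid", 1, 4),
    ("2f_linear", 2, 0),
    ("2f_1sigmoid", 2, 1),
    ("2f_4sigmoid", 2, 4),
)


def benchmark_suite(seed: int, n_subjects: int = 1000) -> list[SimulatedDataset]:
    """The six study conditions, 8 items per factor, sigmoid items last per block."""
    suite = []
    for i, (cname, n_fac, n_sig) in enumerate(BENCHMARK_CONDITIONS):
        spec = make_spec(n_factors=n_fac, n_sigmoid_per_factor=n_sig)
        ds_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % 2**31)
        suite.append(simulate_dataset(spec, n_subjects, seed=ds_seed, name=cname))
    return suite


# ---------------------------------------------------------------------------
# delimited-text round trip


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write responses/scores CSVs and a JSON sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = dataset.n_items
    resp = pd.DataFrame(dataset.responses, columns=[f"item_{j+1}" for j in range(p)])
    scores = pd.DataFrame(
        dataset.true_scores,
        columns=[f"factor_{k+1}" for k in range(dataset.true_scores.shape[1])],
    )
    paths = {
        "responses": outdir / "responses.csv",
        "scores": outdir / "true_scores.csv",
        "spec": outdir / "spec.json",
    }
    # %.17g keeps float64 round trips lossless
    resp.to_csv(paths["responses"], index=False, float_format="%.17g")
    scores.to_csv(paths["scores"], index=False, float_format="%.17g")
    sidecar = {"spec": dataset.spec.to_dict(), "seed": dataset.seed, "name": dataset.name}
    paths["spec"].write_text(json.dumps(sidecar, indent=2))
    return paths


def read_dataset(outdir: str | Path) -> SimulatedDataset:
    """Read back the triplet written by :func:`write_dataset`."""
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "spec.json").read_text())
    responses = pd.read_csv(
        outdir / "responses.csv", float_precision="round_trip"
    ).to_numpy(dtype=float)
    scores = pd.read_csv(
        outdir / "true_scores.csv", float_precision="round_trip"
    ).to_numpy(dtype=float)
    return SimulatedDataset(
        responses=responses,
        true_scores=scores,
        spec=MeasurementSpec.from_dict(sidecar["spec"]),
        seed=sidecar["seed"],
        name=sidecar.get("name", ""),
    )
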