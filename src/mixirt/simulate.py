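"""Population parameters and response simulation for the Monte Carlo design.

The shipped fixture (``data/generating_parameters.csv``) holds the generating
parameters of two three-class population models — the rmGPCM-3 and the
mPCM-3, each with 5 items and 11 response categories — together with a step
mask (``italic``) marking, per class and item, the five adjacent-category
parameters reused in the 6-category conditions, and a ``low_confidence``
column for typographically ambiguous source cells.

The full design crosses model type (rmGPCM / mPCM), test length (5 / 15
items), number of categories (11 / 6) and latent mixture (3 / 2 classes);
:func:`derive_condition` produces the generating parameter set of any cell,
and :func:`generate_dataset` simulates rating-scale responses from it.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .model import ModelSpec, ParameterSet, class_proportions, log_prob_table

__all__ = [
    "GeneratingFixture",
    "ConditionConfig",
    "ResponseMatrix",
    "load_fixture",
    "load_generating_fixture",
    "derive_condition",
    "generate_dataset",
    "replication_seed",
]

FIXTURE_NAME = "generating_parameters.csv"
FIXTURE_SHA256 = "3b09c1a4f68fffb3a899330ef1ea73c2a325f1a4fc5ebca969675cc1a129dade"

#: class-size logit of the second class in the two-class mixture conditions
TWO_CLASS_LOGIT = 0.75

MODEL_TYPES = ("rmGPCM", "mPCM")


@dataclass(frozen=True)
class GeneratingFixture:
    """Verbatim population parameters plus the 6-category step mask.

    ``subset_mask[model]`` is a boolean (G, I, S) array with exactly five True
    steps per (class, item); ``low_confidence[model]`` flags cells whose
    source typography was ambiguous.
    """

    parameters: dict  # model -> ParameterSet
    subset_mask: dict  # model -> bool array (G, I, S)
    low_confidence: dict  # model -> bool array (G, I, S)


@dataclass(frozen=True)
class ConditionConfig:
    """One cell of the simulation design."""

    model_type: str
    n_items: int = 5
    n_categories: int = 11
    true_classes: int = 3
    sample_size: int = 500
    n_replications: int = 50
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}")
        if self.n_items not in (5, 15):
            raise ValueError("n_items must be 5 or 15")
        if self.n_categories not in (6, 11):
            raise ValueError("n_categories must be 6 or 11")
        if self.true_classes not in (2, 3):
            raise ValueError("true_classes must be 2 or 3")
        if self.sample_size < 100:
            raise ValueError("sample_size must be >= 100")

    @property
    def condition_id(self) -> str:
        return (f"{self.model_type}-{self.true_classes}_{self.n_items}i"
                f"_{self.n_categories}c_N{self.sample_size}")

    @property
    def equal_discrimination(self) -> bool:
        return self.model_type == "mPCM"

    def model_spec(self, n_classes: int | None = None) -> ModelSpec:
        return ModelSpec(
            n_items=self.n_items,
            n_categories=self.n_categories,
            n_classes=self.true_classes if n_classes is None else n_classes,
            equal_discrimination=self.equal_discrimination,
        )


@dataclass
class ResponseMatrix:
    """Simulated N x I category responses with the true class labels."""

    responses: np.ndarray  # (N, I) ints in 0..C-1
    true_class: np.ndarray  # (N,) ints in 1..G
    seed: int
    condition: ConditionConfig | None = None

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.responses,
            columns=[f"item{i + 1}" for i in range(self.responses.shape[1])],
        )
        frame.insert(0, "true_class", self.true_class)
        frame.insert(0, "id", np.arange(1, self.n_respondents + 1))
        return frame


def _fixture_bytes() -> bytes:
    return resources.files("mixirt.data").joinpath(FIXTURE_NAME).read_bytes()


def load_fixture() -> GeneratingFixture:
    """Load and checksum-verify the shipped generating-parameter fixture."""
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256:
        raise ValueError(
            f"fixture checksum mismatch: expected {FIXTURE_SHA256}, got {digest}"
        )
    table = pd.read_csv(pd.io.common.BytesIO(raw))
    parameters, masks, lowconf = {}, {}, {}
    for model in MODEL_TYPES:
        sub = table[table.model == model]
        db = sub[sub.parameter_type == "delta_beta"]
        g_ = int(db["class"].max())
        i_ = int(db["item"].max())
        s_ = int(db["step"].max())
        delta = np.empty((g_, i_, s_))
        mask = np.zeros((g_, i_, s_), dtype=bool)
        low = np.zeros((g_, i_, s_), dtype=bool)
        idx = (db["class"] - 1, db["item"] - 1, db["step"] - 1)
        delta[idx] = db["value"].to_numpy()
        mask[idx] = db["italic"].to_numpy().astype(bool)
        low[idx] = db["low_confidence"].to_numpy().astype(bool)
        if not np.all(mask.sum(axis=2) == 5):
            raise ValueError("fixture mask must mark exactly 5 steps per item")
        disc = sub[sub.parameter_type == "item_discrimination"]
        scale = sub[sub.parameter_type == "trait_scale"]
        logit = sub[sub.parameter_type == "class_logit"]
        parameters[model] = ParameterSet(
            delta,
            disc.sort_values("item")["value"].to_numpy(),
            scale.sort_values("class")["value"].to_numpy(),
            logit.sort_values("class")["value"].to_numpy(),
        )
        masks[model] = mask
        lowconf[model] = low
    return GeneratingFixture(parameters, masks, lowconf)


def load_generating_fixture(model_type: str) -> ParameterSet:
    """Population :class:`ParameterSet` of one three-class model (verbatim)."""
    if model_type not in MODEL_TYPES:
        raise ValueError(f"model_type must be one of {MODEL_TYPES}")
    return load_fixture().parameters[model_type].copy()


def derive_condition(fixture: GeneratingFixture,
                     config: ConditionConfig) -> ParameterSet:
    """Generating parameters of one design cell.

    15-item tests replicate the five base items three times in order;
    6-category tests keep only the masked steps of each (class, item), in
    their original order; two-class mixtures keep classes 1-2 with class
    logits (0, ``TWO_CLASS_LOGIT``).  The fixture is never mutated.
    """
    base = fixture.parameters[config.model_type]
    mask = fixture.subset_mask[config.model_type]
    delta = base.delta_beta.copy()
    disc = base.item_discrimination.copy()
    scale = base.trait_scale.copy()
    logit = base.class_logit.copy()

    if config.n_categories == 6:
        g_, i_, _ = delta.shape
        delta = delta[mask].reshape(g_, i_, 5)
    if config.n_items == 15:
        delta = np.tile(delta, (1, 3, 1))
        disc = np.tile(disc, 3)
    if config.true_classes == 2:
        delta = delta[:2]
        scale = scale[:2]
        logit = np.array([0.0, TWO_CLASS_LOGIT])
    return ParameterSet(delta, disc, scale, logit)


def replication_seed(base_seed: int, condition_id: str, replication: int) -> int:
    """Deterministic per-replication seed: base_seed XOR CRC32(condition, rep)."""
    tag = f"{condition_id}:{replication}".encode()
    return (int(base_seed) ^ zlib.crc32(tag)) & 0x7FFFFFFF


def generate_dataset(params: ParameterSet, n: int, seed: int,
                     condition: ConditionConfig | None = None,
                     trait_scale_is_variance: bool = False) -> ResponseMatrix:
    """Simulate ``n`` respondents from a mixture adjacent-category model.

    Per respondent: latent class ~ multinomial(class proportions), trait
    z ~ N(0, 1) scaled by the class trait scale, responses drawn per item
    from the category probabilities.  Bit-reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pi = class_proportions(params.class_logit)
    classes = rng.choice(params.n_classes, size=n, p=pi)
    z = rng.standard_normal(n)
    responses = np.empty((n, params.n_items), dtype=np.int64)
    u = rng.random((n, params.n_items))
    for g in range(params.n_classes):
        members = np.nonzero(classes == g)[0]
        if members.size == 0:
            continue
        # (Q=members, I, C) probabilities at each member's own trait draw
        logp = log_prob_table(params, z[members], trait_scale_is_variance)[g]
        cdf = np.cumsum(np.exp(logp), axis=-1)
        responses[members] = (u[members, :, None] > cdf).sum(axis=-1)
    responses = np.clip(responses, 0, params.n_categories - 1)
    return ResponseMatrix(responses, classes + 1, int(seed), condition)


def model_implied_marginals(params: ParameterSet, grid,
                            trait_scale_is_variance: bool = False) -> np.ndarray:
    """Model-implied marginal category distribution per item, (I, C)."""
    pi = class_proportions(params.class_logit)
    table = np.exp(log_prob_table(params, grid.nodes, trait_scale_is_variance))
    return np.einsum("g,q,gqic->ic", pi, grid.weights, table)
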