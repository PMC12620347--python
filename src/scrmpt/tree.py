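"""Simplified-conjoint-recognition (SCR) multinomial processing tree.

The SCR paradigm probes associative memory with three probe types —
``intact`` (the studied picture–word pair), ``related`` (the picture with a
gist word of the studied target) and ``unrelated`` (the picture with a new,
semantically unrelated word) — and three matching response options.  The MPT
model decomposes the response probabilities into latent retrieval and
guessing processes:

* ``Vi``, ``Vr`` — probability of retrieving the *verbatim* trace given an
  intact / related probe.  Verbatim retrieval yields the correct response.
* ``Gi``, ``Gr`` — probability of retrieving the *gist* trace when verbatim
  retrieval fails.  In the gist state the participant guesses "intact" with
  probability ``a`` and "related" with ``1 - a``.
* ``b`` — probability of guessing the probe is old (intact or related) when
  neither trace is retrieved; the final intact/related guess then uses the
  bias ``ab`` ("intact" with probability ``ab``).

Two variants are supported: the *greene* variant frees ``ab`` as a separate
bias, the *original* variant aliases ``ab`` to ``a`` (one "intact" bias
regardless of gist retrieval).  Unrelated probes share no gist with studied
material by construction of the paradigm, so their subtree contains only the
guessing branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProbeType",
    "ResponseType",
    "ModelVariant",
    "MPTParameters",
    "CountTable",
    "TreePath",
    "category_probabilities",
    "enumerate_tree_paths",
    "simulate_counts",
    "log_likelihood",
]


class ProbeType(str, Enum):
    """Probe type shown at test, in canonical order."""

    INTACT = "intact"
    RELATED = "related"
    UNRELATED = "unrelated"


class ResponseType(str, Enum):
    """Participant response option, same canonical order as probes."""

    INTACT = "intact"
    RELATED = "related"
    UNRELATED = "unrelated"


#: canonical orderings used for every table / vector in the package
PROBE_ORDER: tuple[ProbeType, ...] = tuple(ProbeType)
RESPONSE_ORDER: tuple[ResponseType, ...] = tuple(ResponseType)


class ModelVariant(str, Enum):
    """Which bias structure the tree uses.

    ``greene``: the "intact" bias after entering the old-guessing state
    (``ab``) is a free parameter, distinct from the post-gist bias ``a``.
    ``original``: a single bias ``a`` applies in both states (``ab`` is
    aliased to ``a``).
    """

    GREENE = "greene"
    ORIGINAL = "original"


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0.0 or value > 1.0:
        raise ValueError(f"parameter {name!r} must lie in [0, 1]; got {value!r}")
    return value


@dataclass(frozen=True)
class MPTParameters:
    """Branch probabilities of the SCR tree.

    ``ab`` is the bias to guess "intact" after entering the old-guessing
    state ``b`` (printed "ab" in the literature — a parameter, not a
    product).  With ``constraint_gi_eq_gr`` the shared gist parameter
    ``G = Gi = Gr`` is enforced (the configuration reported for the greene
    variant).
    """

    vi: float
    vr: float
    gi: float
    gr: float
    a: float
    ab: float
    b: float
    constraint_gi_eq_gr: bool = False

    def __post_init__(self) -> None:
        for name in ("vi", "vr", "gi", "gr", "a", "ab", "b"):
            _check_unit(name, getattr(self, name))
        if self.constraint_gi_eq_gr and self.gi != self.gr:
            raise ValueError(
                "constraint_gi_eq_gr=True requires gi == gr exactly; "
                f"got gi={self.gi}, gr={self.gr}"
            )

    @classmethod
    def constrained(
        cls, vi: float, vr: float, g: float, a: float, ab: float, b: float
    ) -> "MPTParameters":
        """Build parameters with the shared gist constraint Gi == Gr == g."""
        return cls(vi=vi, vr=vr, gi=g, gr=g, a=a, ab=ab, b=b, constraint_gi_eq_gr=True)

    def resolve(self, variant: ModelVariant) -> "MPTParameters":
        """Return parameters with variant aliasing applied.

        Under the original variant ``ab`` must equal ``a`` (it is the same
        bias); a conflicting explicit value is an error rather than being
        silently overwritten.
        """
        variant = ModelVariant(variant)
        if variant is ModelVariant.ORIGINAL and self.ab != self.a:
            raise ValueError(
                "original variant aliases ab to a; "
                f"got ab={self.ab} != a={self.a} (set ab=a explicitly)"
            )
        return self

    def as_dict(self) -> dict[str, float]:
        return {
            "Vi": self.vi,
            "Vr": self.vr,
            "Gi": self.gi,
            "Gr": self.gr,
            "a": self.a,
            "ab": self.ab,
            "b": self.b,
        }


@dataclass(frozen=True)
class TreePath:
    """One root-to-leaf path: branch labels, its probability, the response."""

    branches: tuple[str, ...]
    probability: float
    response: ResponseType


def _probs_from_columns(
    vi: np.ndarray,
    vr: np.ndarray,
    gi: np.ndarray,
    gr: np.ndarray,
    a: np.ndarray,
    ab: np.ndarray,
    b: np.ndarray,
) -> np.ndarray:
    """Vectorised closed-form category probabilities.

    Input arrays broadcast to a common shape ``(...,)``; output has shape
    ``(..., 3 probes, 3 responses)`` in canonical order.
    """
    shape = np.broadcast(vi, vr, gi, gr, a, ab, b).shape
    out = np.empty(shape + (3, 3), dtype=float)
    old_i = b * ab          # guess old then "intact"
    old_r = b * (1.0 - ab)  # guess old then "related"
    new = 1.0 - b
    # intact probe
    out[..., 0, 0] = vi + (1 - vi) * gi * a + (1 - vi) * (1 - gi) * old_i
    out[..., 0, 1] = (1 - vi) * gi * (1 - a) + (1 - vi) * (1 - gi) * old_r
    out[..., 0, 2] = (1 - vi) * (1 - gi) * new
    # related probe
    out[..., 1, 0] = (1 - vr) * gr * a + (1 - vr) * (1 - gr) * old_i
    out[..., 1, 1] = vr + (1 - vr) * gr * (1 - a) + (1 - vr) * (1 - gr) * old_r
    out[..., 1, 2] = (1 - vr) * (1 - gr) * new
    # unrelated probe (guessing-only subtree)
    out[..., 2, 0] = old_i
    out[..., 2, 1] = old_r
    out[..., 2, 2] = new
    return out


def probability_matrix(params: MPTParameters, variant: ModelVariant) -> np.ndarray:
    """Full (3 probes x 3 responses) probability matrix in canonical order."""
    p = params.resolve(variant)
    return _probs_from_columns(
        np.float64(p.vi),
        np.float64(p.vr),
        np.float64(p.gi),
        np.float64(p.gr),
        np.float64(p.a),
        np.float64(p.ab),
        np.float64(p.b),
    )


def category_probabilities(
    params: MPTParameters,
    probe: ProbeType,
    variant: ModelVariant = ModelVariant.GREENE,
) -> np.ndarray:
    """Closed-form response probabilities for one probe type.

    Returns a 3-vector over (intact, related, unrelated) responses that sums
    to 1 within floating tolerance and equals the sum of path probabilities
    from :func:`enumerate_tree_paths` per terminal response.
    """
    probe = ProbeType(probe)
    mat = probability_matrix(params, variant)
    return mat[PROBE_ORDER.index(probe)]


def enumerate_tree_paths(
    params: MPTParameters,
    probe: ProbeType,
    variant: ModelVariant = ModelVariant.GREENE,
) -> list[TreePath]:
    """Enumerate every root-to-leaf path of the tree for one probe.

    The per-path probability is the product of its branch probabilities;
    summing within terminal response reproduces
    :func:`category_probabilities` and the total mass is 1.  Serves as the
    independent path-enumeration oracle for the closed forms.
    """
    probe = ProbeType(probe)
    p = params.resolve(variant)
    I, R, U = ResponseType.INTACT, ResponseType.RELATED, ResponseType.UNRELATED

    def guess_paths(prefix: tuple[str, ...], mass: float) -> list[TreePath]:
        return [
            TreePath(prefix + ("b", "ab"), mass * p.b * p.ab, I),
            TreePath(prefix + ("b", "1-ab"), mass * p.b * (1 - p.ab), R),
            TreePath(prefix + ("1-b",), mass * (1 - p.b), U),
        ]

    if probe is ProbeType.INTACT:
        paths = [TreePath(("Vi",), p.vi, I)]
        gist = (1 - p.vi) * p.gi
        paths += [
            TreePath(("1-Vi", "Gi", "a"), gist * p.a, I),
            TreePath(("1-Vi", "Gi", "1-a"), gist * (1 - p.a), R),
        ]
        paths += guess_paths(("1-Vi", "1-Gi"), (1 - p.vi) * (1 - p.gi))
    elif probe is ProbeType.RELATED:
        paths = [TreePath(("Vr",), p.vr, R)]
        gist = (1 - p.vr) * p.gr
        paths += [
            TreePath(("1-Vr", "Gr", "a"), gist * p.a, I),
            TreePath(("1-Vr", "Gr", "1-a"), gist * (1 - p.a), R),
        ]
        paths += guess_paths(("1-Vr", "1-Gr"), (1 - p.vr) * (1 - p.gr))
    else:
        paths = guess_paths((), 1.0)
    return paths


@dataclass
class CountTable:
    """Response counts indexed (probe type x response type).

    The sufficient statistic of the multinomial tree likelihood: a 3x3
    nonnegative integer array in canonical (intact, related, unrelated)
    order on both axes.
    """

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3), dtype=np.int64)
    )

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValueError(f"counts must have shape (3, 3); got {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            arr = np.round(arr).astype(np.int64)
        self.counts = arr.astype(np.int64)

    @property
    def totals(self) -> np.ndarray:
        """Per-probe trial counts (length-3 vector)."""
        return self.counts.sum(axis=1)

    def __add__(self, other: "CountTable") -> "CountTable":
        return CountTable(self.counts + other.counts)

    @classmethod
    def from_responses(
        cls, probes: Iterable[str], responses: Iterable[str]
    ) -> "CountTable":
        counts = np.zeros((3, 3), dtype=np.int64)
        for probe, resp in zip(probes, responses, strict=True):
            i = PROBE_ORDER.index(ProbeType(probe))
            j = RESPONSE_ORDER.index(ResponseType(resp))
            counts[i, j] += 1
        return cls(counts)


def simulate_counts(
    params: MPTParameters,
    totals: Sequence[int],
    variant: ModelVariant = ModelVariant.GREENE,
    seed: int | np.random.Generator | None = None,
) -> CountTable:
    """Draw a CountTable from the tree: one multinomial per probe type.

    ``totals`` gives the trial count per probe in canonical order.
    Reproducible under a fixed ``seed`` (an int or a Generator).
    """
    totals = np.asarray(totals)
    if totals.shape != (3,):
        raise ValueError("totals must be a length-3 sequence (one per probe)")
    if np.any(totals < 0):
        raise ValueError("totals must be nonnegative")
    rng = np.random.default_rng(seed)
    mat = probability_matrix(params, variant)
    counts = np.stack(
        [rng.multinomial(int(n), mat[i]) for i, n in enumerate(totals)]
    )
    return CountTable(counts)


def log_likelihood(
    params: MPTParameters,
    data: CountTable,
    variant: ModelVariant = ModelVariant.GREENE,
) -> float:
    """Multinomial log-likelihood sum(count * log p) over the 9 cells.

    Multinomial coefficients (constant in the parameters) are omitted.
    Returns ``-inf`` only when a cell with positive count has probability 0;
    cells with zero count contribute 0 regardless of their probability.
    """
    mat = probability_matrix(params, variant)
    counts = data.counts
    with np.errstate(divide="ignore"):
        logp = np.log(mat)
    mask = counts > 0
    if np.any(np.isneginf(logp[mask])):
        return float("-inf")
    return float(np.sum(counts[mask] * logp[mask]))
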