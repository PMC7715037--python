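"""The speller's decision core: partition, update, select.

Each query re-partitions the 28-character alphabet (A-Z, space ``_``,
backspace ``<``) among the four boxes so as to maximize the expected
information about the intended character, given the current posterior and
the user's calibration confusion matrix.  The user's response to a query
yields a per-box likelihood vector; a recursive Bayesian update multiplies
each character's posterior by the likelihood of its box; a character is
typed once its posterior strictly exceeds the confidence threshold (85% by
default).

Partition search is heuristic (exact search over 4^28 assignments is
infeasible): characters are placed greedily in decreasing posterior order,
each into the box that maximizes the incremental expected information, then
single-character moves hill-climb to a local optimum.  Ties break by
alphabet order and lowest box index, making the result deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

import numpy as np

from .itr import mutual_information_bits
from .likelihood import ConfusionMatrix

ALPHABET: tuple[str, ...] = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ") + ("_", "<")
BACKSPACE = "<"
SPACE = "_"

DEFAULT_THRESHOLD = 0.85
DEFAULT_MAX_QUERIES = 30
DEFAULT_UNRECOGNIZED_LIMIT = 10

#: Seconds the alphabet is displayed before the first shuffle of a selection.
INITIAL_DISPLAY_S = 5.0
#: Seconds characters pause before each re-shuffle between queries.
INTER_QUERY_PAUSE_S = 2.0

#: Recognition criterion defaults: max normalized box likelihood and the
#: ratio of largest to second-largest likelihood.
RECOGNITION_MIN_MAX = 0.3
RECOGNITION_MIN_RATIO = 1.05


class DegenerateEvidenceError(ValueError):
    """All-zero likelihood vector: no box carries any evidence."""


@dataclass(frozen=True)
class Posterior:
    """Probability per character plus the query count of the current selection."""

    probabilities: np.ndarray
    query_count: int = 0
    unrecognized_count: int = 0
    alphabet: tuple[str, ...] = ALPHABET

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0):
            raise ValueError("posterior entries must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("posterior must sum to 1")
        # Renormalize only when needed: exact threshold semantics depend on
        # stored probabilities not being perturbed by a gratuitous division.
        if abs(p.sum() - 1.0) > 1e-12:
            p = p / p.sum()
        object.__setattr__(self, "probabilities", p)

    @classmethod
    def uniform(cls, alphabet: tuple[str, ...] = ALPHABET) -> "Posterior":
        n = len(alphabet)
        return cls(probabilities=np.full(n, 1.0 / n), alphabet=alphabet)

    @property
    def argmax_character(self) -> str:
        return self.alphabet[int(np.argmax(self.probabilities))]

    @property
    def max_probability(self) -> float:
        return float(self.probabilities.max())


@dataclass(frozen=True)
class Partition:
    """Assignment of each character to one of the boxes."""

    box_of: np.ndarray  # box index per character position
    expected_information_bits: float
    alphabet: tuple[str, ...] = ALPHABET
    n_boxes: int = 4

    def characters_in_box(self, box: int) -> tuple[str, ...]:
        return tuple(
            c for c, b in zip(self.alphabet, self.box_of) if b == box
        )

    def box_of_character(self, character: str) -> int:
        return int(self.box_of[self.alphabet.index(character)])


@dataclass(frozen=True)
class QueryEvidence:
    """Per-box likelihood vector extracted from one user response."""

    likelihoods: np.ndarray
    recognized: bool
    trial_duration_s: float

    def __post_init__(self) -> None:
        lk = np.asarray(self.likelihoods, dtype=float)
        if np.any(lk < 0):
            raise ValueError("likelihoods must be nonnegative")
        object.__setattr__(self, "likelihoods", lk)


def evidence_from_likelihoods(
    likelihoods: np.ndarray,
    trial_duration_s: float,
    min_max: float = RECOGNITION_MIN_MAX,
    min_ratio: float = RECOGNITION_MIN_RATIO,
) -> QueryEvidence:
    """Wrap a raw per-box likelihood vector, applying the recognition criterion.

    Evidence is recognized when the largest normalized likelihood reaches
    ``min_max`` and the largest-to-second-largest ratio reaches ``min_ratio``;
    otherwise the update is skipped and the unrecognized counter advances.
    """
    lk = np.asarray(likelihoods, dtype=float)
    total = lk.sum()
    if total <= 0:
        return QueryEvidence(likelihoods=lk, recognized=False,
                             trial_duration_s=trial_duration_s)
    norm = lk / total
    top2 = np.sort(norm)[-2:]
    ratio = top2[1] / top2[0] if top2[0] > 0 else np.inf
    recognized = bool(top2[1] >= min_max and ratio >= min_ratio)
    return QueryEvidence(likelihoods=lk, recognized=recognized,
                         trial_duration_s=trial_duration_s)


def _xlogx_base2(m: np.ndarray) -> np.ndarray:
    """x log2 x elementwise with 0 log 0 = 0."""
    out = np.zeros_like(m)
    nz = m > 0
    out[nz] = m[nz] * np.log2(m[nz])
    return out


def _partition_information(
    box_mass: np.ndarray, confusion: np.ndarray
) -> float:
    """Expected information of a query: I(intended box; decoded box)."""
    total = box_mass.sum()
    if total <= 0:
        return 0.0
    return mutual_information_bits(box_mass / total, confusion)


def optimize_partition(
    posterior: Posterior,
    confusion: ConfusionMatrix | np.ndarray,
    n_boxes: int = 4,
) -> Partition:
    """Assign characters to boxes maximizing expected information per query.

    Since the objective depends on the assignment only through the per-box
    posterior mass, and mutual information is concave in the input
    distribution, the search seeds by dealing characters (largest posterior
    first) toward the channel's capacity-achieving input distribution
    (Blahut–Arimoto), then hill-climbs with steepest-ascent single-character
    moves and pairwise exchanges.  Information-greedy and mass-balancing
    seedings are climbed as further starts and the best local optimum
    returned.  Deterministic: ties break by alphabet order and lowest box
    index.
    """
    from .itr import nykopp_capacity  # deferred: itr has no engine dependency

    w = confusion.matrix if isinstance(confusion, ConfusionMatrix) else np.asarray(
        confusion, dtype=float
    )
    if w.shape != (n_boxes, n_boxes):
        raise ValueError(
            f"confusion is {w.shape} but n_boxes = {n_boxes}"
        )
    p = posterior.probabilities

    # Stable sort on -p keeps alphabet order among ties.
    order = np.argsort(-p, kind="stable")
    qstar = nykopp_capacity(w).optimal_input_distribution
    best_assignment, best_objective = None, -np.inf
    for seeding in ("target", "greedy", "balance"):
        box_of = _seed_assignment(seeding, order, p, w, n_boxes, qstar)
        box_of, objective = _hill_climb(box_of, p, w, n_boxes)
        if objective > best_objective + 1e-12:
            best_assignment, best_objective = box_of, objective
    return Partition(
        box_of=best_assignment,
        expected_information_bits=best_objective,
        alphabet=posterior.alphabet,
        n_boxes=n_boxes,
    )


def _seed_assignment(
    kind: str,
    order: np.ndarray,
    p: np.ndarray,
    w: np.ndarray,
    n_boxes: int,
    qstar: np.ndarray,
) -> np.ndarray:
    n_chars = len(p)
    box_of = np.full(n_chars, -1, dtype=int)
    box_mass = np.zeros(n_boxes)
    for c in order:
        if kind == "target":
            # Largest remaining deficit toward the capacity-achieving input.
            best_box = int(np.argmax(qstar - box_mass))
        elif kind == "balance":
            best_box = int(np.argmin(box_mass))
        else:
            best_box, best_info = 0, -np.inf
            for b in range(n_boxes):
                box_mass[b] += p[c]
                info = _partition_information(box_mass, w)
                box_mass[b] -= p[c]
                if info > best_info + 1e-15:
                    best_box, best_info = b, info
        box_of[c] = best_box
        box_mass[best_box] += p[c]
    return box_of


def _mi_batch(q: np.ndarray, w: np.ndarray, h_rows: np.ndarray) -> np.ndarray:
    """I(X;Y) in bits for a batch of input distributions (rows of q)."""
    out = q @ w
    with np.errstate(divide="ignore", invalid="ignore"):
        h_out = -np.where(out > 0, out * np.log2(np.where(out > 0, out, 1.0)),
                          0.0).sum(axis=1)
    return h_out - q @ h_rows


def _hill_climb(
    box_of: np.ndarray, p: np.ndarray, w: np.ndarray, n_boxes: int
) -> tuple[np.ndarray, float]:
    """Steepest-ascent local search over moves and pairwise exchanges.

    All candidate neighbors of the current assignment are evaluated in one
    vectorized batch per iteration; box masses always sum to 1, so batched
    mutual information needs no renormalization.  The neighborhood is
    single-character moves, pairwise exchanges and whole-box relabelings
    (swapping two boxes' contents — needed because an asymmetric channel
    makes box identity matter); for small alphabets (<= 12 characters,
    where lumpy posterior masses create packing-type local optima)
    simultaneous two-character relocations are added.
    """
    n_chars = len(p)
    h_rows = -_xlogx_base2(w).sum(axis=1)
    box_of = box_of.copy()

    # Candidate index templates (constant across iterations).
    move_c = np.repeat(np.arange(n_chars), n_boxes)
    move_b = np.tile(np.arange(n_boxes), n_chars)
    pair_c, pair_d = np.triu_indices(n_chars, k=1)
    box_a, box_b = np.triu_indices(n_boxes, k=1)
    use_pair_moves = n_chars <= 12
    if use_pair_moves:
        boxes_sq = np.indices((n_boxes, n_boxes)).reshape(2, -1)
        pm_c = np.repeat(pair_c, n_boxes * n_boxes)
        pm_d = np.repeat(pair_d, n_boxes * n_boxes)
        pm_bc = np.tile(boxes_sq[0], len(pair_c))
        pm_bd = np.tile(boxes_sq[1], len(pair_c))

    while True:
        box_mass = np.bincount(box_of, weights=p, minlength=n_boxes)
        current = float(
            _mi_batch(box_mass[None, :], w, h_rows)[0]
        )

        mv_mask = move_b != box_of[move_c]
        mc, mb = move_c[mv_mask], move_b[mv_mask]
        q_moves = np.tile(box_mass, (len(mc), 1))
        rows = np.arange(len(mc))
        q_moves[rows, box_of[mc]] -= p[mc]
        q_moves[rows, mb] += p[mc]

        sw_mask = box_of[pair_c] != box_of[pair_d]
        sc, sd = pair_c[sw_mask], pair_d[sw_mask]
        q_swaps = np.tile(box_mass, (len(sc), 1))
        rows = np.arange(len(sc))
        delta = p[sc] - p[sd]
        q_swaps[rows, box_of[sc]] -= delta
        q_swaps[rows, box_of[sd]] += delta

        q_relabel = np.tile(box_mass, (len(box_a), 1))
        rows = np.arange(len(box_a))
        q_relabel[rows, box_a] = box_mass[box_b]
        q_relabel[rows, box_b] = box_mass[box_a]

        blocks = [q_moves, q_relabel]
        if len(sc):
            blocks.append(q_swaps)
        if use_pair_moves:
            q_pm = np.tile(box_mass, (len(pm_c), 1))
            rows = np.arange(len(pm_c))
            q_pm[rows, box_of[pm_c]] -= p[pm_c]
            q_pm[rows, pm_bc] += p[pm_c]
            q_pm[rows, box_of[pm_d]] -= p[pm_d]
            q_pm[rows, pm_bd] += p[pm_d]
            blocks.append(q_pm)
        candidates = np.vstack(blocks)
        if len(candidates) == 0:
            return box_of, current
        infos = _mi_batch(candidates, w, h_rows)
        best = int(np.argmax(infos))
        if infos[best] <= current + 1e-12:
            return box_of, current
        n_mv, n_rl, n_sw = len(mc), len(box_a), len(sc)
        if best < n_mv:
            box_of[mc[best]] = mb[best]
        elif best < n_mv + n_rl:
            j = best - n_mv
            a, b = box_a[j], box_b[j]
            in_a = box_of == a
            box_of[box_of == b] = a
            box_of[in_a] = b
        elif best < n_mv + n_rl + n_sw:
            j = best - n_mv - n_rl
            box_of[sc[j]], box_of[sd[j]] = box_of[sd[j]], box_of[sc[j]]
        else:
            j = best - n_mv - n_rl - n_sw
            box_of[pm_c[j]] = pm_bc[j]
            box_of[pm_d[j]] = pm_bd[j]


def bayes_update(
    posterior: Posterior, partition: Partition, evidence: QueryEvidence
) -> Posterior:
    """One recursive Bayesian update: posterior'(c) ∝ posterior(c) · L[box(c)].

    Computed in log space so hundreds of consecutive queries cannot
    underflow.  Unrecognized evidence leaves the distribution unchanged and
    increments the unrecognized counter instead of the query counter.
    """
    if not evidence.recognized:
        return replace(posterior,
                       unrecognized_count=posterior.unrecognized_count + 1)
    lk = evidence.likelihoods
    if np.all(lk == 0):
        raise DegenerateEvidenceError("all-zero likelihood vector")
    with np.errstate(divide="ignore"):
        log_post = np.log(posterior.probabilities) + np.log(lk)[partition.box_of]
    if np.all(np.isinf(log_post) & (log_post < 0)):
        raise DegenerateEvidenceError(
            "evidence assigns zero likelihood to every character with mass"
        )
    log_post -= log_post.max()
    probs = np.exp(log_post)
    probs /= probs.sum()
    return replace(posterior, probabilities=probs,
                   query_count=posterior.query_count + 1)


def select_character(
    posterior: Posterior, threshold: float = DEFAULT_THRESHOLD
) -> str | None:
    """The argmax character iff its probability STRICTLY exceeds the threshold."""
    if posterior.max_probability > threshold:
        return posterior.argmax_character
    return None


class QueryUserModel(Protocol):
    """Produces evidence for one query given the partition and intended character."""

    def respond(self, partition: Partition, intended: str) -> QueryEvidence: ...


@dataclass(frozen=True)
class EngineConfig:
    """Tunables of the selection loop; defaults match the study protocol."""

    threshold: float = DEFAULT_THRESHOLD
    max_queries: int = DEFAULT_MAX_QUERIES
    unrecognized_limit: int = DEFAULT_UNRECOGNIZED_LIMIT
    initial_display_s: float = INITIAL_DISPLAY_S
    inter_query_pause_s: float = INTER_QUERY_PAUSE_S
    recognition_min_max: float = RECOGNITION_MIN_MAX
    recognition_min_ratio: float = RECOGNITION_MIN_RATIO
    n_boxes: int = 4


@dataclass
class SelectionOutcome:
    """Result of one character-selection attempt."""

    character: str | None
    abort_reason: str | None
    n_queries: int
    n_unrecognized: int
    elapsed_s: float
    posterior: Posterior


def run_selection(
    confusion: ConfusionMatrix | np.ndarray,
    user_model: QueryUserModel,
    intended: str,
    config: EngineConfig = EngineConfig(),
    prior: Posterior | None = None,
) -> SelectionOutcome:
    """Run queries until a character is selected or a limit aborts the attempt.

    The loop is optimize_partition -> present query -> evidence ->
    bayes_update -> select_character.  Simulated elapsed time accounts for
    the initial 5 s alphabet display, each query's trial duration, and the
    2 s pause before every re-shuffle after the first query.
    """
    posterior = prior or Posterior.uniform()
    elapsed = config.initial_display_s
    n_queries = 0
    consecutive_unrecognized = 0
    while True:
        if n_queries >= config.max_queries:
            return SelectionOutcome(None, "max-queries", n_queries,
                                    posterior.unrecognized_count, elapsed, posterior)
        if consecutive_unrecognized >= config.unrecognized_limit:
            return SelectionOutcome(None, "unrecognized-input", n_queries,
                                    posterior.unrecognized_count, elapsed, posterior)
        partition = optimize_partition(posterior, confusion, config.n_boxes)
        if n_queries > 0:
            elapsed += config.inter_query_pause_s
        evidence = user_model.respond(partition, intended)
        elapsed += evidence.trial_duration_s
        n_queries += 1
        if evidence.recognized:
            consecutive_unrecognized = 0
        else:
            consecutive_unrecognized += 1
        posterior = bayes_update(posterior, partition, evidence)
        chosen = select_character(posterior, config.threshold)
        if chosen is not None:
            return SelectionOutcome(chosen, None, n_queries,
                                    posterior.unrecognized_count, elapsed, posterior)
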