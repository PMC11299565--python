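"""Perturbation-based region-importance explanations for image classifiers.

To explain a classifier's probability for a target image S, pixels of
atlas regions are swapped in from a *contrast* image S″ — a pool member
the classifier scores lowest for the target's predicted class.  Sampling
many region subsets to replace yields >1000 perturbed images S′ and a
regression dataset (binary replacement indicators → perturbed
probability).  A logistic surrogate fitted to that dataset gives one
importance coefficient per region, per-record fidelity errors
|surrogate − classifier|, and counterfactuals: inclusion-minimal
replacement sets that flip the predicted class.  Averaging coefficients
over many explained predictions ranks the key regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

logger = logging.getLogger(__name__)

__all__ = ["PerturbationRecord", "Explanation", "AggregateImportance",
           "select_contrast", "perturb", "build_perturbation_dataset",
           "fit_surrogate", "find_counterfactuals", "explain",
           "aggregate_importance"]


@dataclass(frozen=True)
class PerturbationRecord:
    replaced_set: frozenset
    probability: float

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass(frozen=True)
class Explanation:
    target_id: str
    contrast_id: str
    region_ids: tuple[int, ...]
    coefficients: dict[int, float]
    intercept: float
    fidelity_errors: np.ndarray
    mean_fidelity_error: float
    max_fidelity_error: float
    counterfactuals: tuple[frozenset, ...]
    surrogate_note: str = ("logistic surrogate on binary replacement "
                           "indicators; probability response; L2-damped IRLS")

    def to_json(self) -> str:
        return json.dumps({
            "target_id": self.target_id, "contrast_id": self.contrast_id,
            "intercept": self.intercept,
            "coefficients": {str(k): v for k, v in self.coefficients.items()},
            "mean_fidelity_error": self.mean_fidelity_error,
            "max_fidelity_error": self.max_fidelity_error,
            "counterfactuals": [sorted(s) for s in self.counterfactuals],
            "surrogate": self.surrogate_note})


@dataclass(frozen=True)
class AggregateImportance:
    mean_importance: dict[int, float]
    ranking: tuple[int, ...]           # descending mean importance
    n_explained: int
    n_failed: int = 0


def select_contrast(classifier_fn, pool: list[np.ndarray],
                    target_predicted_class: int = 1
                    ) -> tuple[int, np.ndarray]:
    """Pool member with the lowest probability for the target's class.

    Returns (index, image).  Ties break to the lowest index.  A singleton
    pool whose member still scores > 0.5 for the target class is accepted
    with a logged warning (it is a weak contrast).
    """
    if not len(pool):
        raise ValueError("contrast pool is empty")
    probs = np.array([float(np.asarray(classifier_fn(img)).reshape(-1)[0])
                      for img in pool])
    if target_predicted_class == 0:
        probs = 1.0 - probs
    idx = int(probs.argmin())
    if len(pool) == 1 and probs[0] > 0.5:
        logger.warning("singleton contrast pool scores %.3f for the target "
                       "class; explanation contrast is weak", probs[0])
    return idx, pool[idx]


def perturb(target: np.ndarray, contrast: np.ndarray, masks,
            replaced_set) -> np.ndarray:
    """Swap the union of the named regions' pixels from contrast into target."""
    target = np.asarray(target, dtype=np.float64)
    contrast = np.asarray(contrast, dtype=np.float64)
    if target.shape != contrast.shape:
        raise ValueError("target and contrast shapes differ")
    if masks.label_canvas.shape != target.shape:
        raise ValueError("mask geometry does not match the images")
    replaced = tuple(replaced_set)
    if not replaced:
        return target.copy()
    union = masks.union_mask(replaced)
    return np.where(union, contrast, target)


def _sample_subsets(region_ids, n: int, rng: np.random.Generator
                    ) -> list[frozenset]:
    """Mixture sampler: singletons, leave-one-out complements, uniform-size
    random subsets; always includes the empty and full sets."""
    ids = list(region_ids)
    r = len(ids)
    subsets = [frozenset(), frozenset(ids)]
    subsets += [frozenset([rid]) for rid in ids]
    subsets += [frozenset(ids) - {rid} for rid in ids]
    while len(subsets) < n:
        size = int(rng.integers(1, r + 1))
        pick = rng.choice(ids, size=size, replace=False)
        subsets.append(frozenset(int(v) for v in pick))
    return subsets


def build_perturbation_dataset(classifier_fn, target, contrast, masks,
                               n: int = 1000, seed: int = 0,
                               batch_size: int = 128
                               ) -> list[PerturbationRecord]:
    """Evaluate the classifier on ``≥ n`` region-swap perturbations.

    ``classifier_fn`` maps a (b, h, w) stack (or a single image) to
    probabilities.  The empty and full replacement sets are always among
    the records, anchoring the surrogate at the target and contrast.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if not masks.region_ids:
        raise ValueError("mask set is empty")
    rng = np.random.default_rng(seed)
    subsets = _sample_subsets(masks.region_ids, n, rng)
    records: list[PerturbationRecord] = []
    for i in range(0, len(subsets), batch_size):
        chunk = subsets[i:i + batch_size]
        batch = np.stack([perturb(target, contrast, masks, s)
                          for s in chunk])
        try:
            probs = np.asarray(classifier_fn(batch), dtype=float).reshape(-1)
        except Exception as exc:
            raise RuntimeError(
                f"classifier failed on subsets {chunk[:3]}...: {exc}") from exc
        records += [PerturbationRecord(s, float(p))
                    for s, p in zip(chunk, probs)]
    return records


def _design(records, region_ids):
    ids = list(region_ids)
    x = np.zeros((len(records), len(ids)))
    col = {rid: j for j, rid in enumerate(ids)}
    for i, rec in enumerate(records):
        for rid in rec.replaced_set:
            x[i, col[rid]] = 1.0
    y = np.array([rec.probability for rec in records])
    return x, y


def _irls_logistic(x: np.ndarray, y: np.ndarray, l2: float = 1e-3,
                   max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """L2-damped IRLS for a logistic model with probability-valued response.

    The response is the classifier's perturbed probability (not a binary
    label), so the cross-entropy is minimised directly; the light ridge
    term keeps separation-prone designs well conditioned.
    """
    xd = np.hstack([np.ones((len(x), 1)), x])
    beta = np.zeros(xd.shape[1])
    pen = l2 * np.eye(xd.shape[1])
    pen[0, 0] = 0.0                         # no penalty on the intercept
    for _ in range(max_iter):
        mu = special.expit(xd @ beta)
        w = np.clip(mu * (1 - mu), 1e-8, None)
        grad = xd.T @ (mu - y) + pen @ beta
        hess = (xd * w[:, None]).T @ xd + pen
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_surrogate(records: list[PerturbationRecord], region_ids,
                  target_id: str = "target", contrast_id: str = "contrast",
                  counterfactuals: tuple[frozenset, ...] = (),
                  l2: float = 1e-3) -> Explanation:
    """Logistic surrogate over replacement indicators → importance scores.

    A region's coefficient is its importance (how strongly replacing it
    moves the class probability); fidelity errors are per-record
    |surrogate-predicted − actual| probabilities.
    """
    x, y = _design(records, region_ids)
    if len(np.unique(x, axis=0)) < 2:
        raise ValueError("design matrix needs ≥ 2 distinct rows")
    beta = _irls_logistic(x, np.clip(y, 1e-7, 1 - 1e-7), l2=l2)
    pred = special.expit(np.hstack([np.ones((len(x), 1)), x]) @ beta)
    fid = np.abs(pred - y)
    ids = tuple(int(r) for r in region_ids)
    coeffs = {rid: float(b) for rid, b in zip(ids, beta[1:])}
    return Explanation(
        target_id=target_id, contrast_id=contrast_id, region_ids=ids,
        coefficients=coeffs, intercept=float(beta[0]), fidelity_errors=fid,
        mean_fidelity_error=float(fid.mean()),
        max_fidelity_error=float(fid.max()),
        counterfactuals=tuple(counterfactuals))


def find_counterfactuals(records: list[PerturbationRecord],
                         threshold: float = 0.5, max_size: int | None = None,
                         prober=None) -> list[frozenset]:
    """Inclusion-minimal replacement sets that flip the predicted class.

    The predicted class comes from the empty-set record.  Candidates are
    the observed flipping subsets, optionally extended by greedy probing
    (``prober(subset) -> probability``) that tries shrinking each flipping
    set one region at a time.  When the contrast shares the target's
    class, no flip exists and an empty list is returned with a log note.
    """
    by_set = {rec.replaced_set: rec.probability for rec in records}
    if frozenset() not in by_set:
        raise ValueError("dataset lacks the empty-set record")
    base_class = int(by_set[frozenset()] >= threshold)

    def flips(p: float) -> bool:
        return int(p >= threshold) != base_class

    flipping = {s for s, p in by_set.items() if flips(p)}
    if not flipping:
        logger.info("no perturbation flips the predicted class; "
                    "no counterfactuals")
        return []

    if prober is not None:
        shrunk = set()
        for s in list(flipping):
            cur = s
            improved = True
            while improved and len(cur) > 1:
                improved = False
                for rid in sorted(cur):
                    cand = cur - {rid}
                    p = by_set.get(cand)
                    if p is None:
                        p = float(prober(cand))
                        by_set[cand] = p
                    if flips(p):
                        cur = cand
                        improved = True
                        break
            shrunk.add(cur)
        flipping |= shrunk
        flipping = {s for s in flipping if flips(by_set[s])}

    if max_size is not None:
        flipping = {s for s in flipping if len(s) <= max_size}
    minimal = [s for s in flipping
               if not any(o < s for o in flipping if o != s)]
    return sorted(minimal, key=lambda s: (len(s), sorted(s)))


def explain(classifier_fn, target, contrast, masks, n: int = 1000,
            seed: int = 0, threshold: float = 0.5,
            target_id: str = "target", contrast_id: str = "contrast",
            probe_counterfactuals: bool = True) -> Explanation:
    """Full explanation of one prediction: dataset, surrogate, counterfactuals."""
    records = build_perturbation_dataset(classifier_fn, target, contrast,
                                         masks, n=n, seed=seed)
    prober = None
    if probe_counterfactuals:
        def prober(subset):
            img = perturb(target, contrast, masks, subset)
            return float(np.asarray(classifier_fn(img[None])).reshape(-1)[0])
    cfs = find_counterfactuals(records, threshold=threshold, prober=prober)
    return fit_surrogate(records, masks.region_ids, target_id=target_id,
                         contrast_id=contrast_id,
                         counterfactuals=tuple(cfs))


def importance_map(masks, coefficients: dict[int, float]) -> np.ndarray:
    """Signed per-pixel importance image for heat-map overlays.

    Each region's pixels take its importance score, normalised by the
    largest absolute score (zero canvas when all scores are zero); save
    with ``matplotlib.pyplot.imsave(..., cmap="coolwarm", vmin=-1, vmax=1)``
    for the conventional red/blue rendering.
    """
    out = np.zeros(masks.label_canvas.shape)
    top = max((abs(v) for v in coefficients.values()), default=0.0)
    if top == 0.0:
        return out
    for rid, score in coefficients.items():
        out[masks.label_canvas == rid] = score / top
    return out


def aggregate_importance(classifier_fn, images: list[np.ndarray],
                         contrast_pool: list[np.ndarray], masks,
                         n_images: int = 100, n_perturbations: int = 1000,
                         seed: int = 0, threshold: float = 0.5
                         ) -> AggregateImportance:
    """Average per-region importance over many explained predictions.

    Explains up to ``n_images`` predictions (each with its own contrast
    selected from the pool) and averages the surrogate coefficients;
    per-image failures are logged, skipped and counted.
    """
    if not len(images):
        raise ValueError("need at least one image to explain")
    ids = masks.region_ids
    sums = {rid: 0.0 for rid in ids}
    n_ok = n_fail = 0
    for i, img in enumerate(images[:n_images]):
        try:
            p0 = float(np.asarray(classifier_fn(
                np.asarray(img)[None])).reshape(-1)[0])
            pred_class = int(p0 >= threshold)
            _, contrast = select_contrast(classifier_fn, contrast_pool,
                                          target_predicted_class=pred_class)
            exp = explain(classifier_fn, img, contrast, masks,
                          n=n_perturbations, seed=seed + i,
                          threshold=threshold, target_id=f"image-{i}",
                          probe_counterfactuals=False)
        except Exception:
            logger.exception("explanation failed for image %d; skipped", i)
            n_fail += 1
            continue
        sign = 1.0 if pred_class == 1 else -1.0
        for rid in ids:
            # replacing an important region moves probability toward the
            # contrast class, so importance = −sign-adjusted coefficient
            sums[rid] += -sign * exp.coefficients[rid]
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("every explanation failed")
    mean_imp = {rid: sums[rid] / n_ok for rid in ids}
    ranking = tuple(sorted(mean_imp, key=lambda r: mean_imp[r],
                           reverse=True))
    return AggregateImportance(mean_importance=mean_imp, ranking=ranking,
                               n_explained=n_ok, n_failed=n_fail)
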