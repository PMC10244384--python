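"""Logistic discrimination of high- vs low-avidity TCRs from CDR3b features.

The probability that a TCR binds its pMHC with high structural avidity
(half-life > 60 s) is modelled as

    p = 1 / (1 + exp(-(b0 + W1*x1 + ... + Wn*xn)))

where each x_i summarises one amino-acid letter over the CDR3b under one of
three encodings:

``exposed_presence``
    1 iff the letter occurs at a CDR3b position whose relative solvent
    exposure exceeds a threshold (default strictly > 0.30) — buried residues
    cannot contact the peptide, so only sufficiently exposed occurrences
    count. Requires an exposure profile from upstream structure modeling.
``presence``
    1 iff the letter occurs anywhere in the CDR3b.
``frequency``
    occurrence count of the letter divided by CDR3b length.

The residue set itself is found by exhaustive search: every subset of 5-8 of
the 20 amino acids is scored by the R^2 of a linear regression of the binary
label on its features, and the best subsets are refit as logistic models and
ranked by ROC AUC and accuracy. The canonical solution uses the residue set
{R, N, D, G, I, L, F} with the exposed-presence encoding.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.metrics import roc_auc_score

from .core import AA_ALPHABET, ExposureProfile, validate_cdr3

Encoding = Literal["presence", "exposed_presence", "frequency"]
ENCODINGS: tuple[Encoding, ...] = ("presence", "exposed_presence", "frequency")

#: Residue set of the canonical classifier.
CANONICAL_RESIDUES = ("R", "N", "D", "G", "I", "L", "F")

#: Solvent-exposure gate: a residue counts as exposed iff its relative
#: exposed fraction is STRICTLY greater than this (an exposure of exactly
#: 30% does not pass).
DEFAULT_EXPOSURE_THRESHOLD = 0.30

#: Fixed tiny L2 penalty applied to the weights (never the bias) so that
#: near-separable panels — the regime of interest, where the classifier makes
#: only one or two errors — still yield finite maximum-likelihood estimates.
DEFAULT_RIDGE = 1e-6


@dataclass(frozen=True)
class FeatureDefinition:
    """Residue set + encoding + exposure threshold defining the feature map."""

    residues: tuple[str, ...] = CANONICAL_RESIDUES
    encoding: Encoding = "exposed_presence"
    exposure_threshold: float = DEFAULT_EXPOSURE_THRESHOLD

    def __post_init__(self) -> None:
        for r in self.residues:
            if r not in AA_ALPHABET:
                raise ValueError(f"unknown residue letter {r!r}")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residues in feature definition")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if not 0.0 < self.exposure_threshold < 1.0:
            raise ValueError("exposure threshold must lie strictly in (0, 1)")

    @property
    def n_features(self) -> int:
        return len(self.residues)


def build_features(
    cdr3b: str,
    fdef: FeatureDefinition,
    exposure: Optional[ExposureProfile] = None,
) -> np.ndarray:
    """Feature vector of one CDR3b under a feature definition.

    For the exposed-presence encoding an exposure profile aligned to the
    CDR3b (same length) is required.
    """
    seq = validate_cdr3(cdr3b)
    if fdef.encoding == "exposed_presence":
        if exposure is None:
            raise ValueError(
                "exposed_presence encoding requires an exposure profile"
            )
        if len(exposure) != len(seq):
            raise ValueError(
                f"exposure profile for {exposure.tcr_id!r} has length "
                f"{len(exposure)} but CDR3b has length {len(seq)}"
            )
        exposed = exposure.exposed_fraction > fdef.exposure_threshold
        return np.array(
            [
                1.0 if any(ch == r and exposed[i] for i, ch in enumerate(seq)) else 0.0
                for r in fdef.residues
            ]
        )
    if fdef.encoding == "presence":
        return np.array([1.0 if r in seq else 0.0 for r in fdef.residues])
    # frequency
    return np.array([seq.count(r) / len(seq) for r in fdef.residues])


def build_feature_matrix(
    cdr3bs: Sequence[str],
    fdef: FeatureDefinition,
    exposures: Optional[Sequence[Optional[ExposureProfile]]] = None,
) -> np.ndarray:
    if exposures is None:
        exposures = [None] * len(cdr3bs)
    return np.stack(
        [build_features(s, fdef, e) for s, e in zip(cdr3bs, exposures)]
    ) if len(cdr3bs) else np.empty((0, fdef.n_features))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class AvidityLogisticModel:
    """Logistic model of the high-avidity label on CDR3b features.

    Parameters
    ----------
    X
        (n, k) feature matrix, one column per residue of the feature
        definition (no intercept column; the bias is handled internally).
    y
        Binary labels, 1 = high avidity (T1/2 > 60 s).
    fdef
        The feature definition the columns of ``X`` realise.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        fdef: Optional[FeatureDefinition] = None,
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, k) and y length n")
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("both avidity classes must be present to fit")
        if fdef is not None and fdef.n_features != X.shape[1]:
            raise ValueError("feature definition does not match X columns")
        self.X, self.y, self.fdef = X, y, fdef

    @classmethod
    def from_panel(
        cls,
        cdr3bs: Sequence[str],
        labels: Sequence[int],
        fdef: FeatureDefinition,
        exposures: Optional[Sequence[Optional[ExposureProfile]]] = None,
    ) -> "AvidityLogisticModel":
        X = build_feature_matrix(cdr3bs, fdef, exposures)
        return cls(X, np.asarray(labels, dtype=float), fdef)

    def fit(
        self, ridge: float = DEFAULT_RIDGE, max_iter: int = 200, tol: float = 1e-10
    ) -> "AvidityLogisticResults":
        """Penalised maximum-likelihood fit by Newton-Raphson.

        Minimises the negative log-likelihood plus ``ridge/2 * ||W||^2``
        (bias unpenalised). With the default tiny ridge the estimates agree
        with unpenalised MLE wherever the MLE exists, and remain finite on
        separable panels, where separability is flagged in the results.
        """
        n, k = self.X.shape
        design = np.hstack([np.ones((n, 1)), self.X])
        pen = np.full(k + 1, ridge)
        pen[0] = 0.0
        theta = np.zeros(k + 1)
        for _ in range(max_iter):
            p = _sigmoid(design @ theta)
            grad = design.T @ (p - self.y) + pen * theta
            w = np.clip(p * (1 - p), 1e-12, None)
            hess = (design * w[:, None]).T @ design + np.diag(pen)
            step = np.linalg.solve(hess, grad)
            theta = theta - step
            if np.max(np.abs(step)) < tol:
                break
        p = _sigmoid(design @ theta)
        w = np.clip(p * (1 - p), 1e-12, None)
        hess = (design * w[:, None]).T @ design + np.diag(pen)
        cov = np.linalg.inv(hess)
        separable = bool(np.all((p > 0.5) == (self.y == 1)) and np.max(np.abs(theta)) > 10)
        return AvidityLogisticResults(
            model=self,
            params=theta,
            cov_params=cov,
            ridge=ridge,
            separable=separable,
        )


@dataclass
class AvidityLogisticResults:
    """Fitted logistic avidity classifier."""

    model: AvidityLogisticModel
    params: np.ndarray
    cov_params: np.ndarray = field(repr=False)
    ridge: float = DEFAULT_RIDGE
    separable: bool = False
    threshold: float = 0.5

    @property
    def b0(self) -> float:
        return float(self.params[0])

    @property
    def weights(self) -> np.ndarray:
        return self.params[1:]

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def fdef(self) -> Optional[FeatureDefinition]:
        return self.model.fdef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"({self.weights.shape[0]} weights)"
            )
        return _sigmoid(self.b0 + X @ self.weights)

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        """High-avidity call iff p STRICTLY exceeds the 0.5 threshold."""
        return (self.predict_proba(X) > self.threshold).astype(int)

    def summary(self) -> str:
        names = ["b0"] + (
            [f"W[{r}]" for r in self.fdef.residues]
            if self.fdef is not None
            else [f"W{i+1}" for i in range(len(self.weights))]
        )
        lines = [
            "Logistic avidity classifier (high iff T1/2 > 60 s)",
            f"  n = {self.model.X.shape[0]}, ridge = {self.ridge:g}"
            + (", SEPARABLE (penalty-stabilised)" if self.separable else ""),
        ]
        if self.fdef is not None:
            lines.append(
                f"  features: {self.fdef.encoding} of "
                f"{{{', '.join(self.fdef.residues)}}}"
                + (
                    f", exposure > {self.fdef.exposure_threshold:.0%}"
                    if self.fdef.encoding == "exposed_presence"
                    else ""
                )
            )
        for name, est, se in zip(names, self.params, self.bse):
            lines.append(f"  {name:8s} {est: 10.4f}  (SE {se:.4f})")
        return "\n".join(lines)


def evaluate_classifier(
    results: AvidityLogisticResults, X: np.ndarray, y: Sequence[int]
) -> dict:
    """ROC AUC (rank statistic, tie-corrected), sensitivity and specificity
    at the model threshold, and the confusion counts.

    With a single-class evaluation set the AUC is undefined and reported as
    None.
    """
    y = np.asarray(y, dtype=int)
    scores = results.predict_proba(X)
    calls = results.predict_label(X)
    tp = int(np.sum((calls == 1) & (y == 1)))
    fn = int(np.sum((calls == 0) & (y == 1)))
    tn = int(np.sum((calls == 0) & (y == 0)))
    fp = int(np.sum((calls == 1) & (y == 0)))
    auc = float(roc_auc_score(y, scores)) if len(np.unique(y)) == 2 else None
    return {
        "auc": auc,
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "accuracy": (tp + tn) / len(y),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


# ---------------------------------------------------------------------------
# Exhaustive residue-subset search
# ---------------------------------------------------------------------------

def n_residue_subsets(sizes: Iterable[int] = (5, 6, 7, 8)) -> int:
    """Number of residue subsets of the given sizes from the 20 amino acids.

    For sizes 5-8 this is 15,504 + 38,760 + 77,520 + 125,970 = 257,754 per
    encoding.
    """
    return sum(math.comb(20, k) for k in sizes)


def _alphabet_feature_matrix(
    cdr3bs: Sequence[str],
    encoding: Encoding,
    exposures: Optional[Sequence[Optional[ExposureProfile]]] = None,
    exposure_threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
) -> np.ndarray:
    """(n, 20) feature matrix over the full amino-acid alphabet."""
    fdef = FeatureDefinition(
        residues=tuple(AA_ALPHABET),
        encoding=encoding,
        exposure_threshold=exposure_threshold,
    )
    return build_feature_matrix(cdr3bs, fdef, exposures)


def _batched_subset_r2(
    X20: np.ndarray, y: np.ndarray, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """R^2 of the linear regression of y on every residue subset of one size.

    Works from the 21x21 Gram matrix (20 letters + intercept) so each subset
    costs one small batched solve. Singular sub-designs (e.g. a letter absent
    from the panel) are stabilised by a 1e-10 diagonal jitter, which leaves
    well-posed R^2 values untouched to far beyond reporting precision.
    """
    n = X20.shape[0]
    design = np.hstack([X20, np.ones((n, 1))])
    gram = design.T @ design
    xty = design.T @ y
    sst = float(np.sum((y - y.mean()) ** 2))
    combos = np.array(list(itertools.combinations(range(20), size)), dtype=np.intp)
    idx = np.concatenate(
        [combos, np.full((combos.shape[0], 1), 20, dtype=np.intp)], axis=1
    )
    sub_gram = gram[idx[:, :, None], idx[:, None, :]]
    sub_gram += 1e-10 * np.eye(size + 1)
    sub_xty = xty[idx]
    beta = np.linalg.solve(sub_gram, sub_xty[..., None])[..., 0]
    yty = float(y @ y)
    sse = yty - 2 * np.einsum("ij,ij->i", beta, sub_xty) + np.einsum(
        "ij,ijk,ik->i", beta, sub_gram, beta
    )
    r2 = 1.0 - sse / sst
    return combos, r2


def exhaustive_feature_search(
    cdr3bs: Sequence[str],
    labels: Sequence[int],
    exposures: Optional[Sequence[Optional[ExposureProfile]]] = None,
    sizes: Sequence[int] = (5, 6, 7, 8),
    encodings: Sequence[Encoding] = ENCODINGS,
    exposure_threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
    top_k: int = 10,
    progress: bool = False,
) -> pd.DataFrame:
    """Exhaustive exploration of residue subsets for the avidity classifier.

    For every subset of each requested size of the 20 amino acids and every
    encoding, the binary label is linearly regressed on the features and the
    fit recorded as R^2 (subsets of 5-8 letters keep 5-9 TCRs per explanatory
    variable on a 48-TCR panel, limiting overfitting). The ``top_k`` subsets
    per encoding are then refit as logistic classifiers and ranked by ROC AUC
    then accuracy.

    Returns a DataFrame with one row per refit candidate, sorted best first,
    with columns residues, encoding, r2, auc, accuracy, n_regressions.
    """
    y = np.asarray(labels, dtype=float)
    rows: list[dict] = []
    total = 0
    for encoding in encodings:
        X20 = _alphabet_feature_matrix(cdr3bs, encoding, exposures, exposure_threshold)
        best: list[tuple[float, tuple[int, ...]]] = []
        for size in sizes:
            combos, r2 = _batched_subset_r2(X20, y, size)
            total += len(combos)
            if progress:  # pragma: no cover - cosmetic
                print(f"  {encoding}: size {size}, {len(combos)} regressions")
            order = np.argsort(r2)[::-1][:top_k]
            best.extend((float(r2[i]), tuple(combos[i])) for i in order)
        best.sort(key=lambda t: (-t[0], t[1]))
        for r2_val, combo in best[:top_k]:
            residues = tuple(AA_ALPHABET[i] for i in combo)
            fdef = FeatureDefinition(
                residues=residues,
                encoding=encoding,
                exposure_threshold=exposure_threshold,
            )
            res = AvidityLogisticModel(X20[:, list(combo)], y, fdef).fit()
            metrics = evaluate_classifier(res, X20[:, list(combo)], y.astype(int))
            rows.append(
                {
                    "residues": "".join(residues),
                    "encoding": encoding,
                    "r2": r2_val,
                    "auc": metrics["auc"],
                    "accuracy": metrics["accuracy"],
                }
            )
    out = pd.DataFrame(rows).sort_values(
        ["auc", "accuracy", "r2"], ascending=False, kind="mergesort"
    )
    out["n_regressions"] = total
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

CvScheme = Literal["leave20out_random", "leave20out_stratified", "leave_one_epitope_out"]


def _fit_or_majority(X, y):
    """Refit on a training fold; degenerate single-class folds fall back to a
    constant majority-class predictor."""
    if len(np.unique(y)) < 2:
        label = int(round(float(np.mean(y))))
        return lambda Xt: np.full(np.atleast_2d(Xt).shape[0], label)
    res = AvidityLogisticModel(X, y).fit()
    return res.predict_label


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    scheme: CvScheme,
    epitopes: Optional[Sequence[str]] = None,
    n_folds: int = 5,
    reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated classification success (accuracy at threshold 0.5).

    ``leave20out_random`` splits the panel into ``n_folds`` random folds
    (~20% each with the default 5); ``leave20out_stratified`` preserves the
    class ratio per fold; ``leave_one_epitope_out`` holds out all TCRs of one
    cognate pMHC at a time, the challenging setting where the model sees no
    example of the held-out specificity. Within each repetition the held-out
    folds are disjoint and their union is the panel.

    Returns a per-fold DataFrame (rep, fold, n_test, success); overall
    success is the weighted mean over rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    rng = np.random.default_rng(seed)
    records = []
    if scheme == "leave_one_epitope_out":
        if epitopes is None:
            raise ValueError("epitope annotations required for leave_one_epitope_out")
        groups = pd.unique(np.asarray(epitopes))
        if len(groups) < 2:
            raise ValueError("leave_one_epitope_out needs at least two epitopes")
        epitopes = np.asarray(epitopes)
        for fold, group in enumerate(groups):
            test = epitopes == group
            predict = _fit_or_majority(X[~test], y[~test])
            success = float(np.mean(predict(X[test]) == y[test]))
            records.append(
                {"rep": 0, "fold": fold, "epitope": group, "n_test": int(test.sum()),
                 "success": success}
            )
    elif scheme in ("leave20out_random", "leave20out_stratified"):
        for rep in range(reps):
            if scheme == "leave20out_random":
                order = rng.permutation(n)
                folds = np.array_split(order, n_folds)
            else:
                folds = [[] for _ in range(n_folds)]
                for cls in np.unique(y):
                    cls_idx = rng.permutation(np.where(y == cls)[0])
                    for i, chunk in enumerate(np.array_split(cls_idx, n_folds)):
                        folds[i].extend(chunk.tolist())
                folds = [np.asarray(f, dtype=int) for f in folds]
            for fold, test_idx in enumerate(folds):
                if len(test_idx) == 0:
                    continue
                mask = np.zeros(n, dtype=bool)
                mask[test_idx] = True
                predict = _fit_or_majority(X[~mask], y[~mask])
                success = float(np.mean(predict(X[mask]) == y[mask]))
                records.append(
                    {"rep": rep, "fold": fold, "n_test": int(mask.sum()),
                     "success": success}
                )
    else:
        raise ValueError(f"unknown cross-validation scheme {scheme!r}")
    return pd.DataFrame(records)


def overall_success(folds: pd.DataFrame) -> float:
    """Fraction of held-out TCRs classified correctly, over all folds."""
    return float(
        (folds["success"] * folds["n_test"]).sum() / folds["n_test"].sum()
    )


# ---------------------------------------------------------------------------
# Amino-acid composition enrichment
# ---------------------------------------------------------------------------

def composition_enrichment(
    high_cdr3bs: Sequence[str], low_cdr3bs: Sequence[str]
) -> pd.DataFrame:
    """Per-amino-acid enrichment of pooled CDR3b composition, high vs low.

    Residue occurrences are pooled within each avidity group; each letter is
    tested with a two-sided Fisher exact test on the 2x2 table (this letter
    vs all others, high vs low group). Returns one row per letter with pooled
    frequencies, their difference (positive = enriched in high), the odds
    ratio, the raw p-value and its Bonferroni correction over the 20 letters.
    """
    if not len(high_cdr3bs) or not len(low_cdr3bs):
        raise ValueError("both avidity groups must be nonempty")

    def pooled_counts(seqs: Sequence[str]) -> dict[str, int]:
        counts = dict.fromkeys(AA_ALPHABET, 0)
        for s in seqs:
            for ch in validate_cdr3(s):
                counts[ch] += 1
        return counts

    hi, lo = pooled_counts(high_cdr3bs), pooled_counts(low_cdr3bs)
    n_hi, n_lo = sum(hi.values()), sum(lo.values())
    rows = []
    for letter in AA_ALPHABET:
        table = [[hi[letter], n_hi - hi[letter]], [lo[letter], n_lo - lo[letter]]]
        odds, p = fisher_exact(table, alternative="two-sided")
        f_hi, f_lo = hi[letter] / n_hi, lo[letter] / n_lo
        rows.append(
            {
                "residue": letter,
                "freq_high": f_hi,
                "freq_low": f_lo,
                "difference": f_hi - f_lo,
                "odds_ratio": odds,
                "p_value": p,
                "p_bonferroni": min(1.0, p * 20),
            }
        )
    return pd.DataFrame(rows).sort_values("p_value", kind="mergesort").reset_index(
        drop=True
    )
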