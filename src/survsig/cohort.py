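"""Cohorts: expression matrix + survival times + censoring flags.

A :class:`Cohort` is the unit every stage of the pipeline consumes: an
``M x n`` matrix of normalized expression values, a survival (or follow-up)
time per sample in months, and a per-sample censoring flag (``True`` means
the patient was alive at last contact, so ``y`` is a lower bound on true
survival).

File dialects
-------------
* Expression: TSV, UTF-8, first column ``sample_id``, remaining columns are
  feature names, one row per sample.
* Clinical: TSV with columns ``patient_id``, ``days``, ``vital_status``
  (``alive``/``dead``, case-insensitive). A ``survival_months`` column, when
  present, takes precedence over ``days`` — it is what :func:`write_cohort`
  emits so that a write/read round trip preserves times bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyJoinError, InsufficientCohortError, ParseError

logger = logging.getLogger(__name__)

#: Average Gregorian month length used to convert clinical day counts.
DAYS_PER_MONTH = 30.44

#: Minimum survival/follow-up time (months) for a sample to be retained.
MIN_SURVIVAL_MONTHS = 1.0


@dataclass
class Cohort:
    """Expression cohort with aligned survival information.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``X``.
    feature_names : list of str
        Unique feature labels, one per column of ``X``.
    X : ndarray, shape (M, n)
        Normalized expression values; finite reals.
    y : ndarray, shape (M,)
        Survival time (uncensored) or follow-up time (censored), in months;
        strictly positive.
    censored : ndarray of bool, shape (M,)
        ``True`` for alive/follow-up samples, ``False`` for observed deaths.
    """

    sample_ids: list[str]
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    censored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(len(self.y), dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        M, n = self.X.shape
        if not (M == len(self.y) == len(self.sample_ids) == len(self.censored)):
            raise ValueError(
                f"row mismatch: X has {M} rows, y has {len(self.y)}, "
                f"{len(self.sample_ids)} sample ids, {len(self.censored)} flags"
            )
        if n != len(self.feature_names):
            raise ValueError(f"X has {n} columns but {len(self.feature_names)} feature names")
        if len(set(self.sample_ids)) != M:
            raise ValueError("duplicate sample_ids")
        if len(set(self.feature_names)) != n:
            raise ValueError("duplicate feature_names")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("expression matrix contains non-finite values")
        if not np.all(self.y > 0):
            raise ValueError("survival times must be strictly positive")

    @classmethod
    def unchecked(cls, sample_ids, feature_names, X, y, censored) -> "Cohort":
        """Construct without invariant checks.

        For staging data that still needs filtering — e.g. a table with
        duplicate patient entries that :func:`filter_training_cohort` will
        collapse. Filtered output always satisfies the invariants.
        """
        c = cls.__new__(cls)
        c.sample_ids = list(sample_ids)
        c.feature_names = list(feature_names)
        c.X = np.asarray(X, dtype=float)
        c.y = np.asarray(y, dtype=float)
        c.censored = np.asarray(censored, dtype=bool)
        return c

    # -- convenience views ------------------------------------------------

    @property
    def M(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in cohort") from None

    def select_features(self, names: list[str]) -> "Cohort":
        """Sub-cohort restricted to ``names`` (order preserved as given)."""
        idx = [self.feature_index(nm) for nm in names]
        return replace(self, feature_names=list(names), X=self.X[:, idx])

    def take(self, rows: np.ndarray) -> "Cohort":
        """Sub-cohort restricted to row indices ``rows``."""
        rows = np.asarray(rows)
        return Cohort(
            sample_ids=[self.sample_ids[i] for i in rows],
            feature_names=list(self.feature_names),
            X=self.X[rows],
            y=self.y[rows],
            censored=self.censored[rows],
        )

    def expression_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.feature_names)


def _read_tsv(path, what: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {what} file {path}: {exc}") from exc


def read_cohort(expression_path, clinical_path, zscale: bool = False) -> Cohort:
    """Read and join an expression TSV and a clinical TSV into a :class:`Cohort`.

    Samples present in only one of the two files are dropped with a logged
    warning. Day counts are converted to months (``days / 30.44``) unless the
    clinical file carries a ``survival_months`` column.

    Parameters
    ----------
    zscale : bool
        If ``True``, z-score each feature column after the join. Off by
        default: expression values are normally used exactly as provided.
    """
    expr = _read_tsv(expression_path, "expression")
    if expr.columns[0] != "sample_id":
        raise ParseError(
            f"expression file {expression_path}: first header column must be "
            f"'sample_id', got {expr.columns[0]!r}"
        )
    clin = _read_tsv(clinical_path, "clinical")
    clin.columns = [c.strip().lower() for c in clin.columns]
    required = {"patient_id", "days", "vital_status"}
    missing = required - set(clin.columns)
    if missing:
        raise ParseError(
            f"clinical file {clinical_path}: missing column(s) {sorted(missing)}"
        )
    if clin["vital_status"].isna().any():
        bad = int(clin["vital_status"].isna().idxmax()) + 2  # header is line 1
        raise ParseError(f"clinical file {clinical_path}: empty vital_status at line {bad}")
    status = clin["vital_status"].astype(str).str.strip().str.lower()
    unknown = ~status.isin(["alive", "dead"])
    if unknown.any():
        bad = int(np.argmax(unknown.to_numpy())) + 2
        raise ParseError(
            f"clinical file {clinical_path}: vital_status must be alive/dead, "
            f"offending line {bad}"
        )
    clin = clin.assign(vital_status=status)
    clin["patient_id"] = clin["patient_id"].astype(str)

    expr_ids = expr["sample_id"].astype(str)
    clin_ids = set(clin["patient_id"])
    seen: set[str] = set()
    common: list[str] = []
    for sid in expr_ids:  # expression-file order, first occurrence wins
        if sid in clin_ids and sid not in seen:
            common.append(sid)
        seen.add(sid)
    if not common:
        raise EmptyJoinError("expression and clinical files share no patient identifiers")
    for label, ids in (("expression", set(expr_ids)), ("clinical", clin_ids)):
        lost = sorted(ids - set(common))
        if lost:
            logger.warning("%d %s-only sample(s) dropped from join: %s",
                           len(lost), label, ", ".join(lost[:5]))

    expr = expr.drop_duplicates("sample_id").set_index(expr_ids.drop_duplicates().values).loc[common]
    clin = clin.drop_duplicates("patient_id").set_index("patient_id").loc[common]

    if "survival_months" in clin.columns:
        y = clin["survival_months"].astype(float).to_numpy()
    else:
        days = clin["days"].astype(float)
        if (days < 0).any():
            raise ParseError(f"clinical file {clinical_path}: negative day count")
        y = (days / DAYS_PER_MONTH).to_numpy()
    censored = (clin["vital_status"] == "alive").to_numpy()

    X = expr.drop(columns=["sample_id"]).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ParseError(f"expression file {expression_path}: missing expression values")
    if zscale:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    return Cohort(
        sample_ids=list(common),
        feature_names=[c for c in expr.columns if c != "sample_id"],
        X=X,
        y=y,
        censored=censored,
    )


def write_cohort(cohort: Cohort, expression_path, clinical_path) -> None:
    """Write a cohort back to the canonical TSV dialect (round-trip safe)."""
    df = cohort.expression_frame()
    # %.17g round-trips IEEE doubles exactly through text
    df.to_csv(expression_path, sep="\t", float_format="%.17g")
    clin = pd.DataFrame(
        {
            "patient_id": cohort.sample_ids,
            "days": np.round(cohort.y * DAYS_PER_MONTH).astype(int),
            "vital_status": np.where(cohort.censored, "alive", "dead"),
            "survival_months": cohort.y,
        }
    )
    clin.to_csv(clinical_path, sep="\t", index=False, float_format="%.17g")


def filter_training_cohort(cohort: Cohort, min_samples: int | None = None) -> Cohort:
    """Apply the training inclusion rules.

    Keeps only uncensored (dead) patients with survival time of at least one
    month, and collapses duplicate patient identifiers to their first
    occurrence. The feature set is untouched.

    Parameters
    ----------
    min_samples : int, optional
        When given, raise :class:`InsufficientCohortError` if fewer samples
        survive the filter (e.g. pass 10 to guarantee 10-fold CV is possible).
    """
    seen: set[str] = set()
    keep: list[int] = []
    for i, sid in enumerate(cohort.sample_ids):
        if sid in seen:
            logger.warning("duplicate patient %s dropped (keeping first occurrence)", sid)
            continue
        seen.add(sid)
        if cohort.censored[i] or cohort.y[i] < MIN_SURVIVAL_MONTHS:
            continue
        keep.append(i)
    out = cohort.take(np.asarray(keep, dtype=int)) if keep else _empty_like(cohort)
    if min_samples is not None and out.M < min_samples:
        raise InsufficientCohortError(
            f"training cohort has {out.M} samples, fewer than required {min_samples}"
        )
    return out


def filter_test_cohort(cohort: Cohort) -> Cohort:
    """Keep only censored (alive) patients with follow-up of at least one month."""
    keep = [
        i
        for i in range(cohort.M)
        if cohort.censored[i] and cohort.y[i] >= MIN_SURVIVAL_MONTHS
    ]
    return cohort.take(np.asarray(keep, dtype=int)) if keep else _empty_like(cohort)


def _empty_like(cohort: Cohort) -> Cohort:
    c = Cohort.__new__(Cohort)
    c.sample_ids = []
    c.feature_names = list(cohort.feature_names)
    c.X = np.empty((0, cohort.n))
    c.y = np.empty(0)
    c.censored = np.empty(0, dtype=bool)
    return c
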