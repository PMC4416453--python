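"""End-to-end diversification meta-analysis of the Rand Flora disjunctions.

Loads the lineage/disjunction table, computes method-of-moments net
diversification rate tables across nested clade levels and an extinction-
fraction grid, builds the expected-diversity envelope of the fastest family
(Asteraceae in the packaged fixture), classifies clades against it, computes
clade-size tail probabilities against each clade's encompassing lineage,
reports stem-crown age gaps, and bins disjunction ages into geological
stages.

All tabular inputs and outputs are pandas DataFrames read/written as TSV;
"NA" marks missing values.  A packaged fixture table transcribes the 21
dated disjunctions and their nesting structure; species richness values that
the source chronograms do not fix are carried with per-row provenance notes
and are marked replaceable.
"""

from __future__ import annotations

import io
import logging
import math
import os
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import bd_moments as bdm
from .errors import DomainError, TableError

__all__ = [
    "LineageTable",
    "StageTable",
    "StageAssignment",
    "load_lineage_table",
    "default_lineage_table",
    "load_stage_table",
    "default_stage_table",
    "compute_rate_table",
    "reference_envelope",
    "classify_clades",
    "clade_probability",
    "stem_crown_gap",
    "assign_stage",
    "timeline",
    "EPSILON_GRID",
    "DEFAULT_SNAP_TOL",
    "GAP_FLAG_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: the extinction-fraction scenarios evaluated throughout the analysis
EPSILON_GRID: tuple[float, ...] = (0.0, 0.5, 0.9)

#: stem-crown gaps larger than this (Myr) are flagged as extinction candidates
GAP_FLAG_THRESHOLD = 10.0

#: timeline boundary-snap tolerance (Myr): disjunction ages are printed at
#: 0.1-0.5 Ma precision, so ages within 0.3 Myr of a stage boundary carry a flag
DEFAULT_SNAP_TOL = 0.3

_COLUMNS = [
    "row_id",
    "parent_id",
    "kind",
    "lineage",
    "name",
    "level",
    "split_type",
    "age_ma",
    "crown_age_ma",
    "stem_age_ma",
    "n_species",
    "source_note",
]
_KINDS = {"clade", "disjunction"}
_SPLIT_TYPES = {"W-E", "W-E&S", "E-S"}
_LEVELS = {
    "disjunct-clade",
    "clade",
    "section",
    "subgenus",
    "genus",
    "tribe",
    "subfamily",
    "family",
}


@dataclass(frozen=True)
class StageAssignment:
    """One age binned into a geological stage."""

    stage: str
    boundary_flag: bool
    nearest_boundary: float


class LineageTable:
    """Validated lineage/disjunction table with an acyclic nesting structure."""

    def __init__(self, df: pd.DataFrame) -> None:
        self.df = df

    @property
    def disjunctions(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "disjunction"]

    @property
    def clades(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "clade"]

    @property
    def families(self) -> pd.DataFrame:
        return self.df[self.df["level"] == "family"]

    def row(self, row_id: str) -> pd.Series:
        sub = self.df[self.df["row_id"] == row_id]
        if sub.empty:
            raise TableError(f"unknown row_id {row_id!r}")
        return sub.iloc[0]


def _basis_age(row: pd.Series, basis: str) -> float | None:
    """Age (Myr) a rate estimate should use for ``row`` on ``basis``.

    A disjunction's dated split age is the crown age of the disjunct pair,
    so crown-basis estimates fall back to ``age_ma`` when no explicit crown
    age is recorded.
    """
    if basis == "crown":
        if pd.notna(row["crown_age_ma"]):
            return float(row["crown_age_ma"])
        if row["kind"] == "disjunction" and pd.notna(row["age_ma"]):
            return float(row["age_ma"])
        return None
    if pd.notna(row["stem_age_ma"]):
        return float(row["stem_age_ma"])
    return None


def load_lineage_table(source: str | os.PathLike | io.IOBase) -> LineageTable:
    """Read and validate a lineage table TSV.

    The header must carry the documented column names; "NA" marks missing
    values.  Validation errors name the offending row.
    """
    if isinstance(source, str) and "\t" in source:
        handle: object = io.StringIO(source)
    else:
        handle = source
    df = pd.read_csv(
        handle,
        sep="\t",
        dtype={"row_id": str, "parent_id": str},
        na_values=["NA"],
        keep_default_na=False,
    )
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableError(f"missing columns: {missing_cols}")
    if df.empty:
        raise TableError("no records")
    if df["row_id"].duplicated().any():
        dupes = df.loc[df["row_id"].duplicated(), "row_id"].tolist()
        raise TableError(f"duplicate row_id values: {dupes}")
    for col in ("age_ma", "crown_age_ma", "stem_age_ma", "n_species"):
        df[col] = pd.to_numeric(df[col], errors="raise")

    by_id = {row.row_id: row for row in df.itertuples()}
    for row in df.itertuples():
        rid = row.row_id
        if row.kind not in _KINDS:
            raise TableError(f"row {rid}: unknown kind {row.kind!r}")
        if row.level not in _LEVELS:
            raise TableError(f"row {rid}: unknown level {row.level!r}")
        if row.kind == "disjunction":
            if row.split_type not in _SPLIT_TYPES:
                raise TableError(
                    f"row {rid}: unknown split_type {row.split_type!r}"
                )
            if not (pd.notna(row.age_ma) and row.age_ma > 0):
                raise TableError(f"row {rid}: disjunction needs age_ma > 0")
        for col in ("age_ma", "crown_age_ma", "stem_age_ma"):
            val = getattr(row, col)
            if pd.notna(val) and val <= 0:
                raise TableError(f"row {rid}: negative or zero {col}")
        if pd.isna(row.age_ma) and pd.isna(row.crown_age_ma) and pd.isna(
            row.stem_age_ma
        ):
            raise TableError(f"row {rid}: no age recorded")
        if (
            pd.notna(row.crown_age_ma)
            and pd.notna(row.stem_age_ma)
            and not row.stem_age_ma > row.crown_age_ma
        ):
            raise TableError(f"row {rid}: stem age must exceed crown age")
        if pd.notna(row.n_species) and row.n_species < 1:
            raise TableError(f"row {rid}: n_species must be >= 1")
        if pd.notna(row.parent_id) and row.parent_id not in by_id:
            raise TableError(
                f"row {rid}: broken nesting link to {row.parent_id!r}"
            )

    # nesting links: acyclic, richness and ages weakly increase outward
    for row in df.itertuples():
        seen = {row.row_id}
        cur = row
        while pd.notna(cur.parent_id):
            if cur.parent_id in seen:
                raise TableError(f"row {row.row_id}: nesting cycle detected")
            seen.add(cur.parent_id)
            cur = by_id[cur.parent_id]
        if pd.notna(row.parent_id):
            parent = by_id[row.parent_id]
            if (
                pd.notna(row.n_species)
                and pd.notna(parent.n_species)
                and parent.n_species < row.n_species
            ):
                raise TableError(
                    f"row {row.row_id}: n exceeds encompassing row "
                    f"{parent.row_id}"
                )
            child_age = _basis_age(pd.Series(row._asdict()), "crown")
            parent_age = _basis_age(pd.Series(parent._asdict()), "crown")
            if (
                child_age is not None
                and parent_age is not None
                and parent_age < child_age
            ):
                raise TableError(
                    f"row {row.row_id}: crown age exceeds encompassing row "
                    f"{parent.row_id}"
                )

    logger.info(
        "lineage table: %d rows (%d disjunctions, %d clades)",
        len(df),
        (df["kind"] == "disjunction").sum(),
        (df["kind"] == "clade").sum(),
    )
    return LineageTable(df)


def default_lineage_table() -> LineageTable:
    """The packaged 21-disjunction fixture table."""
    with resources.files("randflora.data").joinpath("rf_lineages.tsv").open() as fh:
        return load_lineage_table(fh)


# ----------------------------------------------------------------------
# rate tables


def _rate_for(
    row: pd.Series, basis: str, epsilon: float
) -> tuple[float | None, float | None, float | None, str]:
    """(r_hat, n_used, t, note) for one row/basis/epsilon combination."""
    t = _basis_age(row, basis)
    n = row["n_species"]
    if pd.isna(n):
        return None, None, t, "not computable: missing n_species"
    if t is None:
        return None, None, None, f"not computable: missing {basis} age"
    n_used = bdm.two_taxon_adjustment(float(n))
    try:
        if basis == "crown":
            est = bdm.crown_rate(n_used, t, epsilon)
        else:
            est = bdm.stem_rate(n_used, t, epsilon)
    except DomainError as exc:
        return None, n_used, t, f"not computable: {exc}"
    return est.r_hat, n_used, t, ""


def compute_rate_table(
    table: LineageTable,
    epsilons: Sequence[float] = EPSILON_GRID,
    basis: str = "both",
) -> pd.DataFrame:
    """Method-of-moments rates for every row, epsilon and basis.

    Rows lacking the needed age or richness yield explicit "not computable"
    entries rather than being dropped.  The two-taxon diversity adjustment
    (n = 2 -> 2.01) is applied for every epsilon.
    """
    bases = ("crown", "stem") if basis == "both" else (basis,)
    if any(b not in ("crown", "stem") for b in bases):
        raise DomainError(f"basis={basis!r} must be crown, stem or both")
    records = []
    for _, row in table.df.iterrows():
        for b in bases:
            for eps in epsilons:
                r_hat, n_used, t, note = _rate_for(row, b, eps)
                records.append(
                    {
                        "row_id": row["row_id"],
                        "name": row["name"],
                        "level": row["level"],
                        "kind": row["kind"],
                        "basis": b,
                        "epsilon": eps,
                        "n": n_used,
                        "t_ma": t,
                        "r_hat": r_hat,
                        "note": note,
                    }
                )
    return pd.DataFrame.from_records(records)


# ----------------------------------------------------------------------
# reference envelope and classification


def reference_envelope(
    table: LineageTable,
    conf: float = 0.95,
    epsilons: Sequence[float] = EPSILON_GRID,
    times: Sequence[float] | None = None,
    basis: str = "crown",
    reference_level: str = "family",
) -> dict[float, bdm.DiversityEnvelope]:
    """Expected-diversity envelopes at the fastest reference-level rate.

    For each epsilon the reference-level row (family, by default) with the
    highest rate on ``basis`` is selected and a confidence envelope of clade
    size through time is built at its rate; the selected row's name is
    recorded on the envelope.
    """
    ref_rows = table.df[table.df["level"] == reference_level]
    if ref_rows.empty:
        raise TableError(f"no {reference_level}-level rows in table")
    if times is None:
        max_age = float(
            np.nanmax(
                table.df[["age_ma", "crown_age_ma", "stem_age_ma"]].values
            )
        )
        times = np.linspace(0.25, max(max_age * 1.05, 1.0), 200)
    envelopes: dict[float, bdm.DiversityEnvelope] = {}
    for eps in epsilons:
        best_rate, best_name = -math.inf, None
        for _, row in ref_rows.iterrows():
            r_hat, _, _, note = _rate_for(row, basis, eps)
            if note:
                continue
            if r_hat > best_rate:
                best_rate, best_name = r_hat, row["name"]
        if best_name is None:
            raise TableError(
                f"no {reference_level}-level row has a computable {basis} rate"
            )
        env = bdm.diversity_limits(best_rate, eps, times, conf=conf, basis=basis)
        envelopes[eps] = bdm.DiversityEnvelope(
            times=env.times,
            lower=env.lower,
            upper=env.upper,
            conf=conf,
            epsilon=eps,
            r_ref=best_rate,
            basis=env.basis,
            reference=best_name,
        )
        logger.info(
            "reference envelope eps=%.2f: %s (r=%.4f, %s basis)",
            eps,
            best_name,
            best_rate,
            basis,
        )
    return envelopes


def _bounds_at(env: bdm.DiversityEnvelope, t: float) -> tuple[float, float]:
    if t > env.times[-1] + 1e-9:
        raise DomainError(
            f"age {t} Ma outside envelope time grid (max {env.times[-1]}); "
            "extend the grid"
        )
    beta = bdm.geometric_law(env.r_ref, env.epsilon, t).beta if t > 0 else 0.0
    q_lo = (1.0 + env.conf) / 2.0
    q_hi = (1.0 - env.conf) / 2.0
    if env.basis == "crown":
        return (
            bdm._invert_crown_tail(q_lo, beta),
            bdm._invert_crown_tail(q_hi, beta),
        )
    return (
        bdm._invert_stem_tail(q_lo, beta),
        bdm._invert_stem_tail(q_hi, beta),
    )


def classify_clades(
    table: LineageTable,
    envelopes: Mapping[float, bdm.DiversityEnvelope],
    basis: str = "crown",
) -> pd.DataFrame:
    """Map each clade against the reference envelopes.

    Position is "below" when n < lower bound, "above" when n > upper bound,
    "within" otherwise; bounds are treated as a closed interval, so a clade
    exactly on a bound is "within".  Each classified row also carries the
    tail probability of a clade at least its size under the reference rate.
    """
    records = []
    for _, row in table.df.iterrows():
        t = _basis_age(row, basis)
        n = row["n_species"]
        if t is None or pd.isna(n):
            continue
        n = float(n)
        for eps, env in envelopes.items():
            if env.basis != basis:
                raise DomainError(
                    f"envelope for eps={eps} has basis {env.basis!r}, "
                    f"classification requested {basis!r}"
                )
            lower, upper = _bounds_at(env, t)
            if n < lower:
                position = "below"
            elif n > upper:
                position = "above"
            else:
                position = "within"
            tail_fn = bdm.prob_geq_crown if basis == "crown" else bdm.prob_geq_stem
            try:
                tail_p = tail_fn(int(n), env.r_ref, eps, t)
            except DomainError:
                tail_p = math.nan
            gap = (
                float(row["stem_age_ma"] - row["crown_age_ma"])
                if pd.notna(row["stem_age_ma"]) and pd.notna(row["crown_age_ma"])
                else math.nan
            )
            records.append(
                {
                    "row_id": row["row_id"],
                    "name": row["name"],
                    "kind": row["kind"],
                    "basis": basis,
                    "epsilon": eps,
                    "t_ma": t,
                    "n": n,
                    "lower": lower,
                    "upper": upper,
                    "position": position,
                    "tail_probability": tail_p,
                    "stem_crown_gap": gap,
                    "reference": env.reference,
                }
            )
    return pd.DataFrame.from_records(records)


def clade_probability(
    table: LineageTable,
    basis: str = "crown",
    epsilons: Sequence[float] = EPSILON_GRID,
) -> pd.DataFrame:
    """Probability of each disjunct clade's size given its encompassing rate.

    For every disjunction row, the encompassing row's rate is recomputed at
    each epsilon on ``basis`` and the tail probability of a clade at least
    the observed size over the disjunct clade's own age is reported (raw;
    no multiplicity correction is applied).
    """
    if basis not in ("crown", "stem"):
        raise DomainError(f"basis={basis!r} must be crown or stem")
    tail_fn = bdm.prob_geq_crown if basis == "crown" else bdm.prob_geq_stem
    records = []
    for _, row in table.disjunctions.iterrows():
        if pd.isna(row["parent_id"]):
            raise TableError(
                f"row {row['row_id']}: no encompassing row for probability"
            )
        parent = table.row(row["parent_id"])
        t = _basis_age(row, basis)
        n = row["n_species"]
        for eps in epsilons:
            r_enc, _, t_enc, note = _rate_for(parent, basis, eps)
            prob = math.nan
            if note:
                note_out = f"encompassing rate {note}"
            elif t is None or pd.isna(n):
                note_out = f"not computable: missing {basis} age or n"
            elif r_enc <= 0.0:
                note_out = "not computable: encompassing rate <= 0"
            else:
                prob = tail_fn(int(n), r_enc, eps, t)
                note_out = ""
            records.append(
                {
                    "row_id": row["row_id"],
                    "name": row["name"],
                    "encompassing": parent["name"],
                    "basis": basis,
                    "epsilon": eps,
                    "n": n,
                    "t_ma": t,
                    "r_encompassing": r_enc if not note else math.nan,
                    "probability": prob,
                    "note": note_out,
                }
            )
    return pd.DataFrame.from_records(records)


def stem_crown_gap(
    table: LineageTable, flag_threshold: float = GAP_FLAG_THRESHOLD
) -> pd.DataFrame:
    """Stem minus crown age per row, sorted descending, flagging long gaps.

    Rows missing either age are skipped with a log notice.  Gaps above
    ``flag_threshold`` (Myr) mark candidates for historically high
    extinction.
    """
    records = []
    for _, row in table.df.iterrows():
        if pd.isna(row["crown_age_ma"]) or pd.isna(row["stem_age_ma"]):
            logger.info("row %s skipped: missing crown or stem age", row["row_id"])
            continue
        gap = float(row["stem_age_ma"] - row["crown_age_ma"])
        records.append(
            {
                "row_id": row["row_id"],
                "name": row["name"],
                "crown_age_ma": float(row["crown_age_ma"]),
                "stem_age_ma": float(row["stem_age_ma"]),
                "gap_myr": gap,
                "flagged": gap > flag_threshold,
            }
        )
    out = pd.DataFrame.from_records(records)
    if not out.empty:
        out = out.sort_values("gap_myr", ascending=False).reset_index(drop=True)
    return out


# ----------------------------------------------------------------------
# geological stages


class StageTable:
    """Ordered, contiguous geological stages with decreasing Ma bounds."""

    def __init__(self, df: pd.DataFrame) -> None:
        self.df = df

    @property
    def oldest(self) -> float:
        return float(self.df["older_ma"].iloc[0])

    @property
    def youngest(self) -> float:
        return float(self.df["younger_ma"].iloc[-1])

    def boundaries(self) -> np.ndarray:
        return np.concatenate(
            [self.df["older_ma"].values[:1], self.df["younger_ma"].values]
        ).astype(float)


def load_stage_table(source: str | os.PathLike | io.IOBase) -> StageTable:
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t")
    for col in ("stage", "older_ma", "younger_ma"):
        if col not in df.columns:
            raise TableError(f"stage table missing column {col!r}")
    if df.empty:
        raise TableError("stage table has no rows")
    for row in df.itertuples():
        if not row.older_ma > row.younger_ma:
            raise TableError(f"stage {row.stage}: bounds not decreasing")
    for up, lo in zip(df.itertuples(), df[1:].itertuples()):
        if not math.isclose(up.younger_ma, lo.older_ma, rel_tol=1e-9):
            raise TableError(
                f"stages {up.stage} and {lo.stage} are not contiguous"
            )
    return StageTable(df.reset_index(drop=True))


def default_stage_table() -> StageTable:
    """International Chronostratigraphic Chart stages, Burdigalian-Pleistocene."""
    with resources.files("randflora.data").joinpath("ics_stages.tsv").open() as fh:
        return load_stage_table(fh)


def assign_stage(
    age: float, stages: StageTable, snap_tol: float = 0.0
) -> StageAssignment:
    """Bin one age (Ma) into its geological stage.

    Intervals are half-open ``[older, younger)`` on the backward time axis:
    an age equal to a stage's older bound belongs to that stage.  Ages within
    ``snap_tol`` Myr of any boundary are additionally flagged as boundary
    cases.  Ages outside the table's overall span raise an error.
    """
    age = float(age)
    if age > stages.oldest or age < stages.youngest:
        raise TableError(
            f"age {age} Ma outside stage table span "
            f"[{stages.youngest}, {stages.oldest}]"
        )
    chosen = None
    for row in stages.df.itertuples():
        if row.younger_ma < age <= row.older_ma:
            chosen = row.stage
            break
    if chosen is None:  # age == youngest bound exactly
        chosen = stages.df["stage"].iloc[-1]
    nearest = float(np.min(np.abs(stages.boundaries() - age)))
    return StageAssignment(
        stage=chosen, boundary_flag=nearest <= snap_tol, nearest_boundary=nearest
    )


def timeline(
    table: LineageTable,
    stages: StageTable | None = None,
    snap_tol: float = DEFAULT_SNAP_TOL,
) -> pd.DataFrame:
    """Stage label (plus boundary flag) for every disjunction row."""
    if stages is None:
        stages = default_stage_table()
    records = []
    for _, row in table.disjunctions.iterrows():
        assignment = assign_stage(float(row["age_ma"]), stages, snap_tol=snap_tol)
        records.append(
            {
                "row_id": row["row_id"],
                "name": row["name"],
                "split_type": row["split_type"],
                "age_ma": float(row["age_ma"]),
                "stage": assignment.stage,
                "boundary_flag": assignment.boundary_flag,
                "nearest_boundary_myr": assignment.nearest_boundary,
            }
        )
    return pd.DataFrame.from_records(records)
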