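"""Total-flag-sum (TFS) classification of dual-treatment expression patterns.

A gene measured in a 2x2 treatment design (testosterone, MAA, both, vehicle)
is profiled by four competitive hybridizations:

    1. testosterone vs. control
    2. MAA vs. control
    3. testosterone+MAA vs. testosterone
    4. testosterone+MAA vs. MAA

Each comparison yields a signed fold-change and a p-value; a comparison is
*called* up (1), down (2) or null (0) against combined thresholds
(|fold| > 2 and p < 0.005 by default, both strict).  The four calls are
summarised in a TFS code "W.d1d2d3d4" where the whole number W is the sum of
binary flags 1, 2, 4, 8 for the comparisons with a non-null call, and the four
digits give the direction per comparison.  For example up-regulation on
comparisons 1 and 4 only is "9.1001" (9 = 1 + 8).

The 27 codes that admit a clean interaction interpretation are grouped into
classes: I (independent responses, no interaction), IIa-IIc (one treatment
enhances the other's response, or mutually), IIIa-IIId (one treatment blocks
the other's response).  All remaining non-null codes are "other".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPARISON_LABELS: dict[int, str] = {
    1: "testosterone vs control",
    2: "MAA vs control",
    3: "testosterone+MAA vs testosterone",
    4: "testosterone+MAA vs MAA",
}

N_COMPARISONS = 4

_TEXT_RE = re.compile(r"^(\d{1,2})\.([012])([012])([012])([012])$")


@dataclass(frozen=True)
class Thresholds:
    """Combined significance thresholds for a single comparison call.

    fold_min : minimum signed-fold magnitude, strict (default 2, i.e. |fold|>2)
    p_max    : maximum p-value, strict (default 0.005, i.e. p<0.005)
    """

    fold_min: float = 2.0
    p_max: float = 0.005

    def __post_init__(self) -> None:
        if not self.fold_min > 1:
            raise ValueError(f"fold_min must be > 1, got {self.fold_min}")
        if not 0 < self.p_max < 1:
            raise ValueError(f"p_max must be in (0, 1), got {self.p_max}")


@dataclass(frozen=True, order=True)
class TfsCode:
    """A TFS code: four direction digits plus the derived binary flag sum."""

    digits: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.digits) != N_COMPARISONS or any(
            d not in (0, 1, 2) for d in self.digits
        ):
            raise ValueError(f"digits must be four values in {{0,1,2}}: {self.digits!r}")

    @property
    def whole(self) -> int:
        """Sum of binary flags 2^(k-1) over comparisons k with a non-null call."""
        return sum(1 << k for k, d in enumerate(self.digits) if d != 0)

    @property
    def text(self) -> str:
        """Canonical fixed-format text, e.g. "6.0220" (trailing zeros kept)."""
        return f"{self.whole}.{''.join(str(d) for d in self.digits)}"

    @property
    def is_null(self) -> bool:
        return all(d == 0 for d in self.digits)

    @classmethod
    def from_text(cls, text: str) -> "TfsCode":
        m = _TEXT_RE.match(text.strip())
        if m is None:
            raise ValueError(f"malformed TFS code: {text!r}")
        digits = tuple(int(d) for d in m.groups()[1:])
        code = cls(digits)  # type: ignore[arg-type]
        if code.whole != int(m.group(1)):
            raise ValueError(
                f"inconsistent TFS code {text!r}: digits imply whole part {code.whole}"
            )
        return code

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True)
class InteractionClass:
    """Interaction-class label with a human-readable description."""

    label: str
    description: str


_CLASS_DESCRIPTIONS: dict[str, str] = {
    "I": "no interaction between testosterone and MAA",
    "IIa": "MAA enhances the response to testosterone",
    "IIb": "testosterone enhances the response to MAA",
    "IIc": "mutual enhancement between testosterone and MAA",
    "IIIa": "MAA blocks the response to testosterone",
    "IIIb": "testosterone blocks the response to MAA",
    "IIIc": "MAA blocks the testosterone response, MAA alone inactive",
    "IIId": "testosterone blocks the MAA response, testosterone alone inactive",
    "other": "pattern outside the named interaction taxonomy",
}

# The 27 named codes of the interaction taxonomy.
CLASS_TABLE: dict[str, str] = {
    # Class I: independent responses
    "9.1001": "I", "9.2002": "I", "6.0110": "I", "6.0220": "I",
    "3.1100": "I", "3.2200": "I", "15.2112": "I",
    # Class IIa: MAA enhances the testosterone response
    "8.0001": "IIa", "8.0002": "IIa", "14.0111": "IIa", "14.0222": "IIa",
    # Class IIb: testosterone enhances the MAA response
    "4.0010": "IIb", "4.0020": "IIb", "13.1011": "IIb", "13.2022": "IIb",
    # Class IIc: mutual enhancement
    "15.1111": "IIc", "15.2222": "IIc", "12.0011": "IIc", "12.0022": "IIc",
    # Class IIIa/IIIb: one agent blocks the other's own response
    "1.1000": "IIIa", "1.2000": "IIIa",
    "2.0100": "IIIb", "2.0200": "IIIb",
    # Class IIIc/IIId: blocking without single-agent activity
    "5.1020": "IIIc", "5.2010": "IIIc",
    "10.0102": "IIId", "10.0201": "IIId",
}

CLASS_ORDER = ["I", "IIa", "IIb", "IIc", "IIIa", "IIIb", "IIIc", "IIId"]


def call_significance(fold: float, p: float, thresholds: Thresholds | None = None) -> int:
    """Call one comparison: 1 = up, 2 = down, 0 = not significant.

    Both thresholds are strict: |fold| must exceed ``fold_min`` and p must be
    below ``p_max``.  ``fold`` is a signed fold-change with |fold| >= 1.
    """
    th = thresholds or Thresholds()
    if not np.isfinite(fold) or not np.isfinite(p):
        return 0
    if p < th.p_max:
        if fold > th.fold_min:
            return 1
        if fold < -th.fold_min:
            return 2
    return 0


def call_significance_array(
    fold: np.ndarray, p: np.ndarray, thresholds: Thresholds | None = None
) -> np.ndarray:
    """Vectorised :func:`call_significance`; NaNs call 0."""
    th = thresholds or Thresholds()
    fold = np.asarray(fold, dtype=float)
    p = np.asarray(p, dtype=float)
    sig = (p < th.p_max) & np.isfinite(fold) & np.isfinite(p)
    out = np.zeros(fold.shape, dtype=int)
    out[sig & (fold > th.fold_min)] = 1
    out[sig & (fold < -th.fold_min)] = 2
    return out


def compute_tfs(calls: Sequence[int]) -> TfsCode:
    """Build the TFS code from four direction calls in {0,1,2}."""
    return TfsCode(tuple(int(c) for c in calls))  # type: ignore[arg-type]


def assign_class(code: TfsCode | str) -> InteractionClass:
    """Look a TFS code up in the 27-entry interaction taxonomy."""
    text = code.text if isinstance(code, TfsCode) else TfsCode.from_text(code).text
    label = CLASS_TABLE.get(text, "other")
    return InteractionClass(label, _CLASS_DESCRIPTIONS[label])


def expected_false_positives(n_tests: int, alpha: float) -> int:
    """Number of tests expected to pass by chance, rounded to nearest integer."""
    if n_tests < 0:
        raise ValueError("n_tests must be >= 0")
    return int(math.floor(n_tests * alpha + 0.5))


def apparent_fdr(expected: int, observed: int) -> float:
    """Apparent false discovery rate, percent, to 2 decimals: 100*expected/observed."""
    if observed <= 0:
        raise ValueError("observed must be > 0")
    return round(100.0 * expected / observed, 2)


def rounded_percent(part: float, total: float) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    return int(math.floor(100.0 * part / total + 0.5))


def classify_probes(
    comparison_results: Mapping[int, pd.DataFrame],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Merge four per-comparison result tables into per-probe TFS assignments.

    Each value of ``comparison_results`` (keyed 1..4) is a table with columns
    ``probe_id, gene_id, fold, p`` (extra columns ignored).  A probe missing
    from a comparison (no usable measurement) is treated as not significant
    there.  Returns one row per probe: probe_id, gene_id, fold_1..4, p_1..4,
    call_1..4, tfs, tfs_class, min_p.
    """
    th = thresholds or Thresholds()
    missing = [k for k in range(1, N_COMPARISONS + 1) if k not in comparison_results]
    if missing:
        raise ValueError(f"missing comparison results for: {missing}")

    merged: pd.DataFrame | None = None
    for k in range(1, N_COMPARISONS + 1):
        t = comparison_results[k][["probe_id", "gene_id", "fold", "p"]].rename(
            columns={"fold": f"fold_{k}", "p": f"p_{k}"}
        )
        if merged is None:
            merged = t
        else:
            merged = merged.merge(
                t, on="probe_id", how="outer", suffixes=("", f"_{k}")
            )
            # consolidate gene_id across comparisons
            other = f"gene_id_{k}"
            if other in merged.columns:
                merged["gene_id"] = merged["gene_id"].fillna(merged[other])
                merged = merged.drop(columns=other)
    assert merged is not None
    merged = merged.sort_values("probe_id", kind="mergesort").reset_index(drop=True)

    calls = []
    for k in range(1, N_COMPARISONS + 1):
        c = call_significance_array(
            merged[f"fold_{k}"].to_numpy(), merged[f"p_{k}"].to_numpy(), th
        )
        merged[f"call_{k}"] = c
        calls.append(c)
    call_mat = np.stack(calls, axis=1)
    merged["tfs"] = [compute_tfs(row).text for row in call_mat]
    merged["tfs_class"] = [assign_class(TfsCode(tuple(row))).label for row in call_mat]
    p_mat = merged[[f"p_{k}" for k in range(1, N_COMPARISONS + 1)]].to_numpy()
    with np.errstate(invalid="ignore"):
        merged["min_p"] = np.nanmin(p_mat, axis=1)
    return merged


def collapse_redundant(assignments: pd.DataFrame) -> pd.DataFrame:
    """Collapse same-gene probes that share an identical TFS code.

    Array platforms carry redundant probes for many genes.  When two or more
    probes of one gene show the same expression pattern across all four
    comparisons (identical TFS code), a single representative probe is kept:
    the one with the smallest minimum p-value over the four comparisons, ties
    broken by lexicographic probe_id.  Probes of the same gene with
    *different* codes are all retained — only same-pattern redundancy is
    collapsed.  Probes without a gene assignment are dropped (gene-level
    output).  Idempotent.

    ``assignments`` needs columns gene_id, probe_id, tfs, min_p; all columns
    are carried through.
    """
    required = {"gene_id", "probe_id", "tfs", "min_p"}
    missing = required - set(assignments.columns)
    if missing:
        raise ValueError(f"assignments missing columns: {sorted(missing)}")
    df = assignments[
        assignments["gene_id"].notna() & (assignments["gene_id"] != "")
    ].copy()
    df = df.sort_values(
        ["gene_id", "tfs", "min_p", "probe_id"], kind="mergesort"
    )
    collapsed = df.groupby(["gene_id", "tfs"], as_index=False, sort=True).head(1)
    n_redundant = len(df) - len(collapsed)
    collapsed = collapsed.sort_values(
        ["gene_id", "probe_id"], kind="mergesort"
    ).reset_index(drop=True)
    collapsed.attrs["n_redundant_removed"] = n_redundant
    return collapsed


@dataclass
class ClassSummary:
    """Counts of genes of interest per TFS group and per interaction class.

    *Genes of interest* are genes with at least one non-null call (TFS code
    != "0.0000"); they form the denominator of the class percentages.
    """

    by_group: pd.DataFrame        # columns: tfs_class, description, tfs, n_genes
    by_class: pd.DataFrame        # columns: tfs_class, n_genes, n_groups, percent
    n_of_interest: int
    n_classified: int
    n_other: int
    n_other_groups: int

    @property
    def percent_classified(self) -> int:
        if self.n_of_interest == 0:
            return 0
        return rounded_percent(self.n_classified, self.n_of_interest)


def summarize_classes(gene_assignments: pd.DataFrame) -> ClassSummary:
    """Tabulate per-gene TFS assignments into the interaction-class summary.

    Null genes ("0.0000") are excluded throughout; percentages are integer
    percentages of the genes of interest.
    """
    df = gene_assignments[gene_assignments["tfs"] != "0.0000"]
    n_interest = len(df)

    by_group = (
        df.groupby(["tfs_class", "tfs"], sort=False).size().reset_index(name="n_genes")
    )
    by_group["description"] = by_group["tfs_class"].map(_CLASS_DESCRIPTIONS)
    order = {lab: i for i, lab in enumerate(CLASS_ORDER + ["other"])}
    by_group = by_group.sort_values(
        ["tfs_class", "tfs"], key=lambda s: s.map(order) if s.name == "tfs_class" else s,
        kind="mergesort",
    ).reset_index(drop=True)[["tfs_class", "description", "tfs", "n_genes"]]

    rows = []
    for label in CLASS_ORDER:
        sub = by_group[by_group["tfs_class"] == label]
        n = int(sub["n_genes"].sum())
        rows.append(
            {
                "tfs_class": label,
                "n_genes": n,
                "n_groups": len(sub),
                "percent": rounded_percent(n, n_interest) if n_interest else 0,
            }
        )
    by_class = pd.DataFrame(rows)
    other = by_group[by_group["tfs_class"] == "other"]
    n_other = int(other["n_genes"].sum())
    return ClassSummary(
        by_group=by_group,
        by_class=by_class,
        n_of_interest=n_interest,
        n_classified=n_interest - n_other,
        n_other=n_other,
        n_other_groups=len(other),
    )
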