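"""Machine-readable transcriptions of the published result tables.

Three fixtures ship with the package:

* ``table1`` — the 31 lncRNAs differentially expressed between normal
  plasma cells and at least three of the four disease entities; per-entity
  direction calls are stored as the *disease-side* direction (up/down/ns),
  with ``normal_dir`` carrying the printed normal-sample arrow (its
  inverse).
* ``table2`` — the 21 lncRNAs with a progressive expression trend across
  the disease stages (asc/desc).
* ``table3`` — the lncRNAs deregulated in MM patients carrying del13,
  del17 or 1q gain, with SAM score d and fold change.

Correlation cells printed as NA are stored as missing values. A JSON
sidecar pins each fixture's sha256 so transcription drift is detected on
load. ``count_by_filter`` formalizes the counting statements made about
these tables as field-constraint queries.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .core import ValidationError

FIXTURES = ("table1", "table2", "table3")
COMPARISONS = ("MGUS", "SMM", "MM", "PCL")
CALLS = ("up", "down", "ns")
TRENDS = ("asc", "desc")
LESIONS = ("del17", "gain1q", "del13")


def _fixture_bytes(name: str) -> bytes:
    return resources.files("lncarray.fixtures").joinpath(f"{name}.tsv").read_bytes()


def _manifest() -> dict:
    raw = resources.files("lncarray.fixtures").joinpath("manifest.json").read_text()
    return json.loads(raw)


def _validate_table1(df: pd.DataFrame) -> None:
    calls = df[list(COMPARISONS)]
    bad = set(calls.to_numpy().ravel()) - set(CALLS)
    if bad:
        raise ValidationError(f"table1: unknown calls {sorted(bad)}")
    if not set(df["normal_dir"]) <= {"up", "down"}:
        raise ValidationError("table1: normal_dir must be up/down")
    n_sig = (calls != "ns").sum(axis=1)
    if (n_sig < 3).any():
        raise ValidationError("table1: every row needs >= 3 significant comparisons")


def _validate_table2(df: pd.DataFrame) -> None:
    bad = set(df["trend"]) - set(TRENDS)
    if bad:
        raise ValidationError(f"table2: unknown trends {sorted(bad)}")


def _validate_table3(df: pd.DataFrame) -> None:
    bad = set(df["lesion"]) - set(LESIONS)
    if bad:
        raise ValidationError(f"table3: unknown lesions {sorted(bad)}")
    if not df["fold_change"].gt(0).all():
        raise ValidationError("table3: fold changes must be positive")


_VALIDATORS = {"table1": _validate_table1, "table2": _validate_table2, "table3": _validate_table3}


def load_fixture(name: str) -> pd.DataFrame:
    """Load, checksum-verify and invariant-check one packaged table.

    table1 additionally gains derived columns ``n_significant`` (non-ns
    comparisons) and ``disease_dir`` (inverse of the printed normal arrow).
    """
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture {name!r} (choose from {FIXTURES})")
    raw = _fixture_bytes(name)
    expected = _manifest()[name]
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected["sha256"]:
        raise ValidationError(f"{name}: checksum mismatch (transcription drift?)")
    import io

    df = pd.read_csv(io.BytesIO(raw), sep="\t", dtype={"lnc_id": str})
    if df["lnc_id"].duplicated().any():
        raise ValidationError(f"{name}: duplicate lnc_ids")
    if len(df) != expected["n_rows"]:
        raise ValidationError(f"{name}: expected {expected['n_rows']} rows, got {len(df)}")
    if name == "table1":
        df[list(COMPARISONS)] = df[list(COMPARISONS)].fillna("ns")
        df["n_significant"] = (df[list(COMPARISONS)] != "ns").sum(axis=1)
        df["disease_dir"] = df["normal_dir"].map({"up": "down", "down": "up"})
    if "in_table1" in df.columns:
        df["in_table1"] = df["in_table1"].astype(bool)
    _VALIDATORS[name](df)
    return df


def count_by_filter(table: pd.DataFrame, **constraints) -> int:
    """Count rows satisfying every field constraint.

    A constraint value may be a scalar (equality), a set/list/tuple
    (membership), a callable (vectorizable predicate applied per value), or
    a ("startswith", prefix) / ("ne", value) operator tuple.
    """
    mask = pd.Series(True, index=table.index)
    for fld, want in constraints.items():
        if fld not in table.columns:
            raise ValidationError(f"unknown field {fld!r}")
        col = table[fld]
        if callable(want):
            mask &= col.map(want).astype(bool)
        elif isinstance(want, tuple) and len(want) == 2 and want[0] in ("startswith", "ne"):
            op, arg = want
            if op == "startswith":
                mask &= col.astype(str).str.startswith(arg)
            else:
                mask &= col != arg
        elif isinstance(want, (set, frozenset, list)):
            mask &= col.isin(list(want))
        else:
            mask &= col == want
    return int(mask.sum())


def headline_counts() -> dict[str, int]:
    """The tables' headline counts, recomputed from the fixtures."""
    t1 = load_fixture("table1")
    t2 = load_fixture("table2")
    t3 = load_fixture("table3")
    return {
        "table1_total": len(t1),
        "table1_common_all_four": count_by_filter(t1, n_significant=4),
        "table1_exactly_three": count_by_filter(t1, n_significant=3),
        "table1_disease_up": count_by_filter(t1, disease_dir="up"),
        "table1_disease_down": count_by_filter(t1, disease_dir="down"),
        "table2_total": len(t2),
        "table2_ascending": count_by_filter(t2, trend="asc"),
        "table2_descending": count_by_filter(t2, trend="desc"),
        "table3_del17": count_by_filter(t3, lesion="del17"),
        "table3_gain1q": count_by_filter(t3, lesion="gain1q"),
        "table3_del13": count_by_filter(t3, lesion="del13"),
        "table3_gain1q_on_1q": count_by_filter(
            t3, lesion="gain1q", chrom_band=("startswith", "1q")
        ),
        "table3_del13_on_chr13": count_by_filter(
            t3, lesion="del13", chrom_band=("startswith", "13")
        ),
    }
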