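"""MM/PBSA energy-component aggregation and per-residue contribution ranking.

End-point binding free-energy bookkeeping in kcal/mol:

    ∆E_MM (= ∆G_gas) = ∆E_ele + ∆E_vdW (+ ∆E_int)
    ∆G_sol           = ∆G_pb + ∆G_np        (or supplied as one column)
    ∆H (= ∆G_total)  = ∆E_MM + ∆G_sol
    ∆G_bind          = ∆H − T∆S             (entropy term optional)

Derived quantities are computed per frame and then summarized as Average,
Std. Dev. (sample SD, n−1 denominator) and Std. Err. of Mean = SD/√n, so
the summation identities hold exactly on the averages.  The entropy term
is optional and absent by default — single-trajectory end-point tables
are conventionally reported without it, with ∆G_total as the headline.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .synthdata import canonical_component

__all__ = [
    "aggregate",
    "sem",
    "rank_residue_contributions",
    "recompute_derived",
    "read_energy_csv",
    "format_summary",
]

_DISPLAY = {
    "dE_vdw": "∆E_vdW", "dE_ele": "∆E_ele", "dE_int": "∆E_int",
    "dG_pb": "∆G_pb", "dG_np": "∆G_np", "dG_solv": "∆G_solv",
    "dG_gas": "∆G_gas", "dG_total": "∆G_total", "dG_bind": "∆G_bind",
    "minus_TdS": "−T∆S",
}


def sem(values) -> float:
    """Standard error of the mean: sample SD (n−1) divided by √n.

    A single observation has no dispersion estimate; n = 1 returns NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    if v.size == 1:
        return float("nan")
    return float(np.std(v, ddof=1) / math.sqrt(v.size))


def _normalize_table(table: pd.DataFrame) -> pd.DataFrame:
    df = table.rename(columns={c: canonical_component(str(c)) for c in table.columns})
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("energy table contains non-finite values")
    return df


def aggregate(table: pd.DataFrame, entropy_term: float | None = None) -> pd.DataFrame:
    """Summarize a per-frame energy-component table.

    Parameters
    ----------
    table
        One row per frame; columns named with the component labels
        (∆E_vdW, ∆E_ele, ∆G_solv, ... or their ASCII aliases).  ∆G_solv
        may be given directly or as ∆G_pb + ∆G_np; ∆E_int defaults to 0
        (it cancels in single-trajectory end-point analysis).
    entropy_term
        Optional −T∆S (kcal/mol); when given, ∆G_bind = ∆G_total + (−T∆S)
        is added to the summary.

    Returns
    -------
    DataFrame indexed by component/derived-quantity with columns
    ``Average``, ``Std. Dev.``, ``Std. Err. of Mean``.
    """
    df = _normalize_table(table)
    if len(df) < 1:
        raise ValueError("energy table must have at least one frame")
    for required in ("dE_vdw", "dE_ele"):
        if required not in df.columns:
            raise ValueError(f"missing required component {_DISPLAY[required]}")
    if "dG_solv" in df.columns:
        solv = df["dG_solv"]
    elif "dG_pb" in df.columns and "dG_np" in df.columns:
        solv = df["dG_pb"] + df["dG_np"]
    else:
        raise ValueError("missing required component ∆G_solv (or ∆G_pb + ∆G_np)")

    per_frame: dict[str, pd.Series] = {}
    order = [c for c in ("dE_vdw", "dE_ele", "dE_int", "dG_pb", "dG_np") if c in df.columns]
    for c in order:
        per_frame[c] = df[c]
    gas = df["dE_vdw"] + df["dE_ele"]
    if "dE_int" in df.columns:
        gas = gas + df["dE_int"]
    per_frame["dG_gas"] = gas
    per_frame["dG_solv"] = solv
    per_frame["dG_total"] = gas + solv
    if entropy_term is not None:
        per_frame["minus_TdS"] = pd.Series(np.full(len(df), float(entropy_term)))
        per_frame["dG_bind"] = per_frame["dG_total"] + float(entropy_term)

    rows = {}
    for key, series in per_frame.items():
        v = series.to_numpy(dtype=float)
        rows[_DISPLAY[key]] = {
            "Average": float(v.mean()),
            "Std. Dev.": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "Std. Err. of Mean": sem(v),
        }
    return pd.DataFrame(rows).T[["Average", "Std. Dev.", "Std. Err. of Mean"]]


def recompute_derived(printed: dict) -> dict:
    """Recompute the derived rows of a published energy table from the rows
    printed above them.

    ``printed`` maps component labels (unicode or ASCII) to their printed
    Average values.  ∆G_gas is recomputed from the component rows; ∆G_total
    from the table's own ∆G_gas row when printed (the layering a reader uses
    to check the table), otherwise from the recomputed value.
    """
    vals = {canonical_component(k): float(v) for k, v in printed.items()
            if _normalize_derived_key(k) is None}
    derived_in = {_normalize_derived_key(k): float(v) for k, v in printed.items()
                  if _normalize_derived_key(k) is not None}
    gas = vals["dE_vdw"] + vals["dE_ele"] + vals.get("dE_int", 0.0)
    solv = vals.get("dG_solv", vals.get("dG_pb", 0.0) + vals.get("dG_np", 0.0))
    total = derived_in.get("dG_gas", gas) + solv
    return {"dG_gas": gas, "dG_total": total}


_DERIVED_ALIASES = {"∆G_gas": "dG_gas", "dG_gas": "dG_gas",
                    "∆G_total": "dG_total", "dG_total": "dG_total"}


def _normalize_derived_key(key: str) -> str | None:
    return _DERIVED_ALIASES.get(key)


def rank_residue_contributions(per_residue: pd.DataFrame,
                               top_n: int | None = None) -> pd.DataFrame:
    """Rank per-residue binding-energy contributions, most favorable first.

    Expects columns ``residue`` (number) and ``energy`` (kcal/mol).
    Sorting is ascending in energy (a large negative contribution binds
    strongest); ties break by residue number.
    """
    if len(per_residue) < 1:
        raise ValueError("need at least one residue")
    df = per_residue.copy()
    if "residue" not in df.columns or "energy" not in df.columns:
        raise ValueError("expected columns 'residue' and 'energy'")
    ranked = df.sort_values(["energy", "residue"], kind="mergesort").reset_index(drop=True)
    ranked.index = ranked.index + 1
    ranked.index.name = "rank"
    return ranked.head(top_n) if top_n else ranked


def read_energy_csv(path) -> pd.DataFrame:
    """Read a per-frame energy-component CSV with unicode or ASCII headers."""
    df = pd.read_csv(path)
    return _normalize_table(df)


def format_summary(summary: pd.DataFrame, title: str = "") -> str:
    """Aligned text rendering of an aggregate summary (4-decimal precision)."""
    lines = []
    if title:
        lines.append(title)
    lines.append(f"{'Energy Component':<18}{'Average':>12}{'Std. Dev.':>12}"
                 f"{'Std. Err. of Mean':>20}")
    for name, row in summary.iterrows():
        semv = row["Std. Err. of Mean"]
        sem_txt = f"{semv:>20.4f}" if np.isfinite(semv) else f"{'n/a':>20}"
        lines.append(
            f"{name:<18}{row['Average']:>12.4f}{row['Std. Dev.']:>12.4f}{sem_txt}"
        )
    return "\n".join(lines)
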