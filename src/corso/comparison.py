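"""Compare simulated flux distributions with experimental flux tables.

Metabolic flux analysis (MFA) experiments report net fluxes through a
reaction network whose names rarely match a reconstruction's ids, so an
optional translation map (with a sign column, since MFA direction
conventions differ) aligns the two before computing Pearson correlation
and sum of squared error, fraction by fraction across a sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats


@dataclass
class IdMap:
    """Experimental-id → (model reaction id, sign) translation."""

    entries: dict[str, tuple[str, float]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMap":
        df = pd.read_csv(path, sep="\t")
        expected = ("exp_id", "model_id", "sign")
        if tuple(df.columns) != expected:
            raise ValueError(f"id map header must be {expected}")
        return cls(
            {str(r.exp_id): (str(r.model_id), float(r.sign))
             for r in df.itertuples(index=False)}
        )


@dataclass
class ComparisonResult:
    fraction: float
    pearson_r: float  # NaN when undefined (zero variance)
    sse: float
    n_matched: int


def align_flux_vectors(
    sim: Mapping[str, float],
    exp: Mapping[str, float],
    id_map: IdMap | None = None,
) -> tuple[list[float], list[float], list[str]]:
    """Pair simulated and experimental fluxes on shared reaction ids.

    Returns (sim values, exp values, unmatched experimental ids), ordered
    by experimental id.  Fewer than two shared ids is an error: neither
    correlation nor a meaningful error sum exists.
    """
    sim_vals, exp_vals, unmatched = [], [], []
    for exp_id in sorted(exp):
        model_id, sign = (exp_id, 1.0)
        if id_map is not None and exp_id in id_map.entries:
            model_id, sign = id_map.entries[exp_id]
        if model_id in sim:
            sim_vals.append(sign * sim[model_id])
            exp_vals.append(exp[exp_id])
        else:
            unmatched.append(exp_id)
    if len(sim_vals) < 2:
        raise ValueError(
            f"only {len(sim_vals)} shared reaction ids after mapping; need ≥ 2"
        )
    return sim_vals, exp_vals, unmatched


def compare(
    pairs: tuple[Sequence[float], Sequence[float]] | tuple[Sequence[float], Sequence[float], Sequence[str]],
    fraction: float = math.nan,
) -> ComparisonResult:
    """Pearson correlation and SSE between paired flux vectors.

    With zero variance in either vector the correlation is undefined and
    reported as NaN; the SSE is still computed.
    """
    sim, exp = pairs[0], pairs[1]
    if len(sim) != len(exp) or len(sim) < 2:
        raise ValueError("need two equally long vectors with ≥ 2 entries")
    sse = float(sum((s - e) ** 2 for s, e in zip(sim, exp)))
    if _variance_zero(sim) or _variance_zero(exp):
        r = math.nan
    else:
        r = float(stats.pearsonr(sim, exp).statistic)
    return ComparisonResult(fraction=fraction, pearson_r=r, sse=sse,
                            n_matched=len(sim))


def _variance_zero(v: Sequence[float]) -> bool:
    return max(v) == min(v)


def compare_sweep(
    solutions,
    exp: Mapping[str, float],
    id_map: IdMap | None = None,
    normalize: str | None = None,
    glc_g6p_id: str | None = None,
) -> pd.DataFrame:
    """Correlation/SSE versus one experimental flux table for every
    solution of a sweep; returns a (fraction, pearson_r, sse, n_matched)
    table."""
    from .corso_solver import normalize_fluxes

    rows = []
    for sol in solutions:
        sim = (
            normalize_fluxes(sol, normalize, glc_g6p_id)
            if normalize
            else sol.net_fluxes
        )
        res = compare(align_flux_vectors(sim, exp, id_map), fraction=sol.fraction)
        rows.append(
            {"fraction": res.fraction, "pearson_r": res.pearson_r,
             "sse": res.sse, "n_matched": res.n_matched}
        )
    return pd.DataFrame(rows)
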