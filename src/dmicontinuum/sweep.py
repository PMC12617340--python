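"""Parameter-sweep driver over selection coefficients, environmental symmetry
and locus number, producing long-format probability tables (the data behind
phase-diagram style surfaces)."""

from __future__ import annotations

import itertools

import pandas as pd

from .dmi import DomainError, p_dmi_env, p_dmi_poly_equal_s, p_dmi_uo

__all__ = ["run_sweep"]

_MODELS = ("uo", "env", "poly")


def run_sweep(
    s_a_values,
    s_b_values=None,
    phi_values=(1.0,),
    n_values=(1,),
    models=("env",),
) -> pd.DataFrame:
    """Evaluate analytic DMI probabilities over a parameter grid.

    Returns a long-format frame with columns (model, s_A, s_B, phi, n, p_dmi)
    covering the Cartesian product of the grids.  Model "uo" ignores phi and
    n; "env" ignores n; "poly" is the equal-s polygenic form, which uses n
    and phi only.  Empty grids are rejected before any computation.
    """
    s_a_values = list(s_a_values)
    s_b_values = list(s_b_values) if s_b_values is not None else list(s_a_values)
    phi_values, n_values, models = list(phi_values), list(n_values), list(models)
    for name, grid in (
        ("s_a_values", s_a_values),
        ("s_b_values", s_b_values),
        ("phi_values", phi_values),
        ("n_values", n_values),
        ("models", models),
    ):
        if not grid:
            raise DomainError(f"empty grid: {name}")
    unknown = [m for m in models if m not in _MODELS]
    if unknown:
        raise DomainError(f"unknown models {unknown}; expected subset of {_MODELS}")

    rows = []
    for model, s_a, s_b, phi, n in itertools.product(
        models, s_a_values, s_b_values, phi_values, n_values
    ):
        if model == "uo":
            p = p_dmi_uo(s_a, s_b)
        elif model == "env":
            p = p_dmi_env(s_a, s_b, phi)
        else:
            p = p_dmi_poly_equal_s(n, phi)
        rows.append(
            {"model": model, "s_A": s_a, "s_B": s_b, "phi": phi, "n": n, "p_dmi": p}
        )
    return pd.DataFrame(rows)
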