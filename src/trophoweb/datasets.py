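"""Packaged reference tables for the Comacchio Lagoon study system.

Three small CSVs ship with the package: the environmental pre/post table
(mean values with their printed percent changes), the published global
metrics of the two aggregated webs, and the taxon -> functional-group
aggregation table with period presence flags.  Loaders return plain pandas
frames (or an :class:`~trophoweb.core.AggregationScheme`).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import AggregationScheme


def _path(name: str):
    return resources.files("trophoweb.data").joinpath(name)


def load_environment_table() -> pd.DataFrame:
    """Environmental variables: pre/post means and printed percent changes.

    ``pre_value`` may carry a detection-limit bound such as ``<1.00``;
    :func:`trophoweb.compare.parse_bounded` turns it into its numeric bound.
    """
    with resources.as_file(_path("comacchio_environment.csv")) as p:
        return pd.read_csv(p, dtype={"pre_value": str, "post_value": str})


def load_global_metrics_table() -> pd.DataFrame:
    """Published global metrics (N, L, D, CL, d, SW) of the aggregated webs."""
    with resources.as_file(_path("comacchio_global_metrics.csv")) as p:
        return pd.read_csv(p)


def load_functional_groups() -> pd.DataFrame:
    """Taxon -> functional group table with PRE/POST presence flags."""
    with resources.as_file(_path("comacchio_functional_groups.csv")) as p:
        return pd.read_csv(p)


def load_aggregation_scheme(period: str | None = None) -> AggregationScheme:
    """The functional-group aggregation scheme, optionally one period only."""
    df = load_functional_groups()
    if period is not None:
        period = period.upper()
        if period not in {"PRE", "POST"}:
            raise ValueError(f"period must be PRE or POST, got {period!r}")
        df = df[df[period.lower()] == "x"]
    return AggregationScheme(dict(zip(df["taxon"], df["functional_group"])))
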