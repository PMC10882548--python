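"""From raw child records to an analysis-ready model frame.

Children are classified from their WHO-standardized anthropometric Z scores:
stunted if height-for-age Z (HAZ) falls strictly below -2, wasted if
weight-for-height Z (WHZ) falls strictly below -2.  Scores beyond +/-6 in
absolute value are treated as biologically implausible outliers and the
record is excluded.  Records with any missing covariate are dropped listwise
and counted.

The model frame bundles the binary outcome pair, the three design matrices
(stunting margin, wasting margin, copula dependence) with their penalty
blocks, and the survey-design columns (sampling weight, cluster, stratum).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .smoothers import SmoothTerm, iid_term, mrf_term, spline_term

#: reference-first level orders for treatment (reference-cell) coding
CATEGORY_ORDERS: dict[str, list] = {
    "sex": ["male", "female"],
    "ethnicity": ["majority", "minority"],
    "maternal_education": ["none", "primary", "secondary", "higher"],
    "maternal_working": [0, 1],
    "wealth_quintile": [1, 2, 3, 4, 5],
    "location": ["urban", "rural"],
    "head_gender": ["male", "female"],
    "toilet_improved": [0, 1],
    "water_on_premise": [0, 1],
    "water_treated": [0, 1],
}

#: default predictor specifications for the two margins and the dependence
DEFAULT_MARGIN_TERMS = [
    "sex", "ethnicity", "maternal_education", "maternal_working",
    "wealth_quintile", "location", "head_gender", "toilet_improved",
    "water_on_premise", "water_treated",
    "s(age_months)", "s(maternal_haz)", "s(maternal_whz)",
    "s(maternal_age_first_birth)",
    "mrf(region)", "iid(region)",
]
DEFAULT_THETA_TERMS = ["mrf(region)"]

_Z_LIMIT = 6.0
_CUTOFF = -2.0


def classify_outcomes(haz: float, whz: float):
    """Classify one child's (HAZ, WHZ) pair into binary (stunted, wasted).

    Returns ``(y_stunt, y_waste)`` or ``None`` when either score lies
    outside [-6, 6] (outlier exclusion; the bounds themselves are retained).
    Non-finite scores raise.
    """
    if not (np.isfinite(haz) and np.isfinite(whz)):
        raise ValueError(f"non-finite Z score: haz={haz}, whz={whz}")
    if abs(haz) > _Z_LIMIT or abs(whz) > _Z_LIMIT:
        return None
    return (int(haz < _CUTOFF), int(whz < _CUTOFF))


def classify_frame(df: pd.DataFrame, *, apply_to_maternal: bool = False
                   ) -> tuple[pd.DataFrame, int]:
    """Vectorized classification + outlier exclusion over a child table.

    Adds ``y_stunt``/``y_waste`` columns; returns the retained frame and the
    number of rows excluded by the +/-6 rule.  ``apply_to_maternal`` extends
    the exclusion to the maternal Z scores (off by default — the exclusion
    rule is stated for child scores).
    """
    haz = df["haz"].to_numpy(dtype=float)
    whz = df["whz"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(haz)) and np.all(np.isfinite(whz))):
        bad = df.index[~(np.isfinite(haz) & np.isfinite(whz))].tolist()
        raise ValueError(f"non-finite child Z scores at rows {bad[:10]}")
    keep = (np.abs(haz) <= _Z_LIMIT) & (np.abs(whz) <= _Z_LIMIT)
    if apply_to_maternal:
        for col in ("maternal_haz", "maternal_whz"):
            if col in df:
                z = df[col].to_numpy(dtype=float)
                keep &= ~(np.abs(z) > _Z_LIMIT)
    out = df.loc[keep].copy()
    out["y_stunt"] = (out["haz"] < _CUTOFF).astype(int)
    out["y_waste"] = (out["whz"] < _CUTOFF).astype(int)
    return out, int((~keep).sum())


# ---------------------------------------------------------------------------
# adjacency IO
# ---------------------------------------------------------------------------

def read_adjacency(path) -> nx.Graph:
    """Read a neighbour-list file: one ``region: n1 n2 ...`` line per region."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            name, _, rest = line.partition(":")
            name = name.strip()
            g.add_node(name)
            for nb in rest.split():
                if nb == name:
                    raise ValueError(f"self-loop on region {name!r}")
                g.add_edge(name, nb.strip())
    return g


def write_adjacency(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for node in sorted(graph.nodes()):
            nbs = " ".join(sorted(graph.neighbors(node)))
            fh.write(f"{node}: {nbs}\n")


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

_S_RE = re.compile(r"^s\((\w+)(?:\s*,\s*k\s*=\s*(\d+))?\)$")


@dataclass
class PenaltyBlock:
    label: str
    sl: slice          # column slice within the predictor's design matrix
    S: np.ndarray      # penalty for that slice
    null_dim: int = 0


@dataclass
class Predictor:
    """One linear predictor: design matrix, column names, penalty blocks."""

    label: str
    X: np.ndarray
    colnames: list[str]
    penalties: list[PenaltyBlock] = field(default_factory=list)
    smooths: dict[str, SmoothTerm] = field(default_factory=dict)
    terms: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _encode_categorical(s: pd.Series, name: str):
    levels = CATEGORY_ORDERS.get(name)
    if levels is None:
        levels = sorted(s.dropna().unique().tolist())
    observed = set(s.dropna().unique().tolist())
    unknown = observed - set(levels)
    if unknown:
        raise ValueError(f"unknown levels {sorted(unknown)} in {name!r}")
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((s == lev).to_numpy(dtype=float))
        names.append(f"{name}[{lev}]")
    return cols, names


def build_predictor(df: pd.DataFrame, terms: list[str], label: str,
                    graph: nx.Graph | None = None, k_default: int = 10
                    ) -> Predictor:
    """Assemble one predictor's design matrix from a term list.

    Terms: bare column names (categorical -> reference-coded indicators,
    numeric -> one linear column), ``s(col)`` / ``s(col, k=..)`` penalized
    splines, ``mrf(region)`` the structured spatial effect, ``iid(region)``
    the unstructured one.  An intercept column is always first.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(intercept)"]
    penalties: list[PenaltyBlock] = []
    smooths: dict[str, SmoothTerm] = {}

    for t in terms:
        m = _S_RE.match(t)
        if m:
            col, kstr = m.group(1), m.group(2)
            k = int(kstr) if kstr else k_default
            x = df[col].to_numpy(dtype=float)
            st = spline_term(x, k=k, label=f"s({col})")
            start = len(names)
            for j in range(st.width):
                names.append(f"s({col}).{j+1}")
            cols.append(st.columns)
            penalties.append(PenaltyBlock(st.label, slice(start, start + st.width),
                                          st.penalty, st.null_dim))
            smooths[st.label] = st
        elif t == "mrf(region)":
            if graph is None:
                raise ValueError("mrf(region) term requires a region graph")
            st = mrf_term(df["region_id"].to_numpy(), graph, label="mrf(region)")
            start = len(names)
            names += [f"mrf.{j+1}" for j in range(st.width)]
            cols.append(st.columns)
            penalties.append(PenaltyBlock(st.label, slice(start, start + st.width),
                                          st.penalty, st.null_dim))
            smooths[st.label] = st
        elif t == "iid(region)":
            levels = sorted(graph.nodes()) if graph is not None else None
            st = iid_term(df["region_id"].to_numpy(), levels=levels,
                          label="iid(region)")
            start = len(names)
            names += [f"iid.{j+1}" for j in range(st.width)]
            cols.append(st.columns)
            penalties.append(PenaltyBlock(st.label, slice(start, start + st.width),
                                          st.penalty, st.null_dim))
            smooths[st.label] = st
        else:
            s = df[t]
            if t in CATEGORY_ORDERS or s.dtype == object or isinstance(
                s.dtype, pd.CategoricalDtype
            ):
                ccols, cnames = _encode_categorical(s, t)
                for c, nm in zip(ccols, cnames):
                    if np.ptp(c) == 0 and len(ccols) == 1:
                        raise ValueError(f"covariate {t!r} is constant")
                    cols.append(c)
                    names.append(nm)
            else:
                x = s.to_numpy(dtype=float)
                if np.ptp(x) == 0:
                    raise ValueError(f"covariate {t!r} is constant")
                cols.append(x)
                names.append(t)

    X = np.column_stack([c if c.ndim == 2 else c.reshape(-1, 1) for c in cols])
    return Predictor(label=label, X=X, colnames=names, penalties=penalties,
                     smooths=smooths, terms=list(terms))


@dataclass
class ModelFrame:
    """Analysis-ready data: outcomes, designs, survey-design vectors."""

    df: pd.DataFrame
    y1: np.ndarray
    y2: np.ndarray
    weights: np.ndarray
    region: np.ndarray
    cluster: np.ndarray
    stratum: np.ndarray
    graph: nx.Graph
    stunt: Predictor
    waste: Predictor
    theta: Predictor
    n_dropped_missing: int = 0
    n_dropped_outlier: int = 0

    @property
    def n(self) -> int:
        return len(self.df)


def build_model_frame(records: pd.DataFrame,
                      stunt_terms: list[str] | None = None,
                      waste_terms: list[str] | None = None,
                      region_graph: nx.Graph | None = None,
                      theta_terms: list[str] | None = None,
                      k_default: int = 10,
                      outlier_maternal: bool = False) -> ModelFrame:
    """Classify, exclude, drop-missing, and build the three design matrices.

    ``records`` must carry either ``haz``/``whz`` (classified here) or
    ready-made ``y_stunt``/``y_waste``.  Every region in the data must be a
    node of ``region_graph``.
    """
    stunt_terms = list(stunt_terms if stunt_terms is not None
                       else DEFAULT_MARGIN_TERMS)
    waste_terms = list(waste_terms if waste_terms is not None
                       else DEFAULT_MARGIN_TERMS)
    theta_terms = list(theta_terms if theta_terms is not None
                       else DEFAULT_THETA_TERMS)
    if region_graph is None:
        raise ValueError("a region adjacency graph is required")

    df = records.copy()
    n_outlier = 0
    if "y_stunt" not in df or "y_waste" not in df:
        df, n_outlier = classify_frame(df, apply_to_maternal=outlier_maternal)

    used_cols = {"y_stunt", "y_waste", "region_id", "weight",
                 "cluster_id", "stratum_id"}
    for t in stunt_terms + waste_terms + theta_terms:
        m = _S_RE.match(t)
        if m:
            used_cols.add(m.group(1))
        elif t not in ("mrf(region)", "iid(region)"):
            used_cols.add(t)
    missing_cols = used_cols - set(df.columns)
    if missing_cols:
        raise KeyError(f"missing columns: {sorted(missing_cols)}")

    before = len(df)
    df = df.dropna(subset=sorted(used_cols))
    n_missing = before - len(df)
    df = df.reset_index(drop=True)

    regions = set(df["region_id"].unique())
    off_graph = regions - set(region_graph.nodes())
    if off_graph:
        raise ValueError(
            f"region(s) not in adjacency graph: {sorted(off_graph)}"
        )
    w = df["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("sampling weights must be positive")

    stunt = build_predictor(df, stunt_terms, "stunting", region_graph, k_default)
    waste = build_predictor(df, waste_terms, "wasting", region_graph, k_default)
    theta = build_predictor(df, theta_terms, "dependence", region_graph, k_default)

    return ModelFrame(
        df=df,
        y1=df["y_stunt"].to_numpy(dtype=int),
        y2=df["y_waste"].to_numpy(dtype=int),
        weights=w,
        region=df["region_id"].to_numpy(),
        cluster=df["cluster_id"].to_numpy(),
        stratum=df["stratum_id"].to_numpy(),
        graph=region_graph,
        stunt=stunt,
        waste=waste,
        theta=theta,
        n_dropped_missing=n_missing,
        n_dropped_outlier=n_outlier,
    )
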