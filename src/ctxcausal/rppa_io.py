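"""Data model and file formats shared by all pipeline stages.

The central container is :class:`RppaDataset`: an abundance matrix
(samples x antibodies) together with per-sample metadata (cell line,
stimulus, inhibitor regime, time in minutes, replicate index, batch id)
and a scale flag (``linear`` or ``log2``).

On disk the canonical layout is *long* format -- one row per
(sample, antibody) pair with columns::

    cell_line, stimulus, inhibitor, time_min, replicate, batch, antibody, value

A *wide* layout (metadata columns followed by one column per antibody) is
accepted for convenience.  Delimiters are inferred from the file extension
(``.csv`` -> comma, ``.tsv``/``.txt`` -> tab).  The first line may be a
comment of the form ``# scale=log2`` recording the measurement scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "IntegrityError",
    "AntibodyInfo",
    "InhibitorRegime",
    "Context",
    "PriorNetwork",
    "RppaDataset",
    "META_COLUMNS",
    "SAMPLE_KEY",
    "read_rppa_table",
    "write_rppa_table",
    "read_prior_network",
    "write_network_outputs",
    "read_config",
    "node_name",
]

#: metadata columns, in canonical order
META_COLUMNS = ["cell_line", "stimulus", "inhibitor", "time_min", "replicate", "batch"]

#: columns that uniquely identify a sample
SAMPLE_KEY = ["cell_line", "stimulus", "inhibitor", "time_min", "replicate"]

CELL_LINES = ("MCF7", "UACC812", "BT20", "BT549")
STIMULI = ("PBS", "FBS", "EGF", "IGF1", "Insulin", "FGF1", "NRG1", "HGF")
ANALYSIS_TIMES = (0.0, 5.0, 15.0, 30.0, 60.0, 120.0, 240.0)


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class IntegrityError(ValueError):
    """A dataset violates an internal invariant (e.g. duplicate sample key)."""


def node_name(target: str, phospho_sites: Sequence[str]) -> str:
    """Map an antibody's target protein and phospho-sites to a network node name.

    The convention is the protein name followed by ``_p<site>`` for each
    site, e.g. ``AKT`` + ``["S473"]`` -> ``"AKT_pS473"``.  Total-protein
    antibodies map to the bare protein name.
    """
    return target + "".join(f"_p{s}" for s in phospho_sites)


@dataclass(frozen=True)
class AntibodyInfo:
    """Annotation for one antibody: its target protein and phospho status."""

    name: str
    target_node: str
    phospho_sites: tuple[str, ...] = ()
    validation_label: str = "validated"

    @property
    def is_phospho(self) -> bool:
        return len(self.phospho_sites) > 0

    @property
    def node(self) -> str:
        return node_name(self.target_node, self.phospho_sites)


@dataclass(frozen=True)
class InhibitorRegime:
    """An inhibitor condition: which compounds, which nodes they block."""

    regime_id: str
    inhibitor_names: tuple[str, ...] = ()
    target_nodes: frozenset[str] = frozenset()
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.is_control and self.target_nodes:
            raise ValueError("control regime must have empty target set")


#: the study's regime panel; PD173074 targets FGFR, which carries no
#: phospho-antibody in the analysis panel (target_nodes left symbolic).
STUDY_REGIMES = (
    InhibitorRegime("DMSO", ("DMSO",), frozenset(), is_control=True),
    InhibitorRegime("AZD8055", ("AZD8055",), frozenset({"mTOR_pS2448"})),
    InhibitorRegime("GSK690693", ("GSK690693",), frozenset({"AKT_pS473", "AKT_pT308"})),
    InhibitorRegime("BEZ235", ("BEZ235",), frozenset({"mTOR_pS2448", "PI3K"})),
    InhibitorRegime("PD173074", ("PD173074",), frozenset({"FGFR"})),
    InhibitorRegime(
        "GSK690693_GSK1120212",
        ("GSK690693", "GSK1120212"),
        frozenset({"AKT_pS473", "AKT_pT308", "MEK1_pS217_S221"}),
    ),
)


@dataclass(frozen=True, order=True)
class Context:
    """A (cell line, stimulus) combination; inhibitors act *within* a context."""

    cell_line: str
    stimulus: str

    def __str__(self) -> str:  # used in file names / table headers
        return f"{self.cell_line}__{self.stimulus}"

    @staticmethod
    def parse(text: str) -> "Context":
        cl, st = text.split("__", 1)
        return Context(cl, st)


@dataclass
class PriorNetwork:
    """A directed prior network over node names (no self-loops)."""

    nodes: set[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        for p, c in self.edges:
            if p == c:
                raise ValueError(f"self-loop {p}->{c} in prior network")
            if p not in self.nodes or c not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: ({p}, {c})")

    def parents_of(self, child: str) -> frozenset[str]:
        return frozenset(p for p, c in self.edges if c == child)

    def adjacency(self, order: Sequence[str]) -> np.ndarray:
        """0/1 matrix A[i, j] = 1 iff edge j -> i (column = parent)."""
        idx = {n: i for i, n in enumerate(order)}
        a = np.zeros((len(order), len(order)))
        for p, c in self.edges:
            if p in idx and c in idx:
                a[idx[c], idx[p]] = 1.0
        return a


@dataclass
class RppaDataset:
    """Abundance matrix plus per-sample metadata.

    Parameters
    ----------
    meta
        One row per sample with columns :data:`META_COLUMNS`.
    values
        Abundances, index-aligned with ``meta``, one column per antibody.
    scale
        ``"linear"`` (non-negative) or ``"log2"``.
    antibodies
        Optional annotations keyed by antibody (column) name.
    excluded
        Sample index -> reason code for samples dropped by QC.
    """

    meta: pd.DataFrame
    values: pd.DataFrame
    scale: str = "linear"
    antibodies: dict[str, AntibodyInfo] = field(default_factory=dict)
    excluded: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise FormatError(f"missing metadata column(s): {', '.join(missing)}")
        if not self.meta.index.equals(self.values.index):
            raise IntegrityError("meta and values indices differ")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and len(self.values) and (self.values.to_numpy() < 0).any():
            raise IntegrityError("negative abundances on linear scale")
        dup = self.meta.duplicated(subset=SAMPLE_KEY)
        if dup.any():
            key = self.meta.loc[dup.idxmax(), SAMPLE_KEY].tolist()
            raise IntegrityError(f"duplicate sample key {tuple(key)}")

    # -- convenience -----------------------------------------------------
    @property
    def antibody_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.meta)

    def contexts(self) -> list[Context]:
        pairs = self.meta[["cell_line", "stimulus"]].drop_duplicates()
        return sorted(Context(r.cell_line, r.stimulus) for r in pairs.itertuples())

    def regime_ids(self) -> list[str]:
        return sorted(self.meta["inhibitor"].unique())

    def subset(self, mask: pd.Series | np.ndarray) -> "RppaDataset":
        return RppaDataset(
            self.meta.loc[mask].copy(),
            self.values.loc[mask].copy(),
            scale=self.scale,
            antibodies=dict(self.antibodies),
        )

    def select_context(self, context: Context) -> "RppaDataset":
        m = (self.meta["cell_line"] == context.cell_line) & (
            self.meta["stimulus"] == context.stimulus
        )
        return self.subset(m)

    def to_log2(self) -> "RppaDataset":
        if self.scale == "log2":
            return self
        vals = self.values.where(self.values > 0)
        n_bad = int(vals.isna().sum().sum() - self.values.isna().sum().sum())
        if n_bad:
            warnings.warn(f"{n_bad} non-positive values set to missing before log2")
        return RppaDataset(
            self.meta.copy(), np.log2(vals), scale="log2", antibodies=dict(self.antibodies)
        )

    def copy(self) -> "RppaDataset":
        return RppaDataset(
            self.meta.copy(),
            self.values.copy(),
            scale=self.scale,
            antibodies=dict(self.antibodies),
            excluded=dict(self.excluded),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_header_scale(path: Path) -> tuple[str | None, int]:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        text = first.lstrip("#").strip()
        if text.startswith("scale="):
            return text.split("=", 1)[1].strip(), 1
        return None, 1
    return None, 0


def _coerce_meta(df: pd.DataFrame, path: Path, skiprows: int) -> pd.DataFrame:
    """Validate/coerce metadata columns; drop unparseable rows with a warning."""
    for col in ("time_min", "replicate"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["time_min"].isna() | (df["time_min"] < 0)
    bad |= df["replicate"].isna() | (df["replicate"] < 1)
    bad |= df[["cell_line", "stimulus", "inhibitor"]].isna().any(axis=1)
    if bad.any():
        # +2: 1-based and one header line (plus any scale comment line)
        lines = [int(i) + 2 + skiprows for i in np.flatnonzero(bad.to_numpy())]
        warnings.warn(
            f"{path.name}: rejected {len(lines)} row(s) with unparseable metadata "
            f"(line numbers {lines[:20]})"
        )
        df = df.loc[~bad]
    df = df.copy()
    df["replicate"] = df["replicate"].astype(int)
    df["batch"] = df["batch"].astype(str)
    return df


def read_rppa_table(
    path: str | Path, dialect: str = "long", scale: str | None = None
) -> RppaDataset:
    """Read an RPPA table in long or wide layout into an :class:`RppaDataset`.

    The scale is taken from an optional ``# scale=...`` header line, or
    from the ``scale`` argument (which wins); the default is ``linear``.
    Rows with unparseable metadata are rejected with a warning naming the
    offending line numbers; duplicate sample keys raise
    :class:`IntegrityError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header_scale, skiprows = _read_header_scale(path)
    df = pd.read_csv(path, sep=_delimiter(path), skiprows=skiprows)
    eff_scale = scale or header_scale or "linear"

    if dialect == "long":
        required = META_COLUMNS + ["antibody", "value"]
    elif dialect == "wide":
        required = META_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing metadata column(s): {', '.join(missing)}")

    df = _coerce_meta(df, path, skiprows)
    if dialect == "long":
        key_cols = SAMPLE_KEY + ["antibody"]
        if df.duplicated(subset=key_cols).any():
            first = df.loc[df.duplicated(subset=key_cols).idxmax(), SAMPLE_KEY].tolist()
            raise IntegrityError(f"duplicate (sample, antibody) record for key {tuple(first)}")
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        meta = df[META_COLUMNS].drop_duplicates(subset=SAMPLE_KEY).reset_index(drop=True)
        wide = df.set_index(SAMPLE_KEY + ["antibody"])["value"].unstack("antibody")
        wide = wide.reindex(pd.MultiIndex.from_frame(meta[SAMPLE_KEY])).reset_index(drop=True)
        wide.columns.name = None
        values = wide
    else:
        ab_cols = [c for c in df.columns if c not in META_COLUMNS]
        meta = df[META_COLUMNS].reset_index(drop=True)
        values = df[ab_cols].apply(pd.to_numeric, errors="coerce").reset_index(drop=True)
    return RppaDataset(meta, values, scale=eff_scale)


def write_rppa_table(data: RppaDataset, path: str | Path, dialect: str = "long") -> None:
    """Write a dataset in long or wide layout; round-trips through
    :func:`read_rppa_table` up to floating-point text precision."""
    path = Path(path)
    sep = _delimiter(path)
    with open(path, "w") as fh:
        fh.write(f"# scale={data.scale}\n")
        if dialect == "long":
            long = data.meta.join(data.values).melt(
                id_vars=META_COLUMNS, var_name="antibody", value_name="value"
            )
            long = long.dropna(subset=["value"])
            long.to_csv(fh, sep=sep, index=False, float_format="%.17g")
        elif dialect == "wide":
            data.meta.join(data.values).to_csv(fh, sep=sep, index=False, float_format="%.17g")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_prior_network(
    path: str | Path, extra_nodes: Iterable[str] = ()
) -> PriorNetwork:
    """Read a directed edge list (``parent<TAB>child``) or SIF
    (``parent relation child``) file.  Self-loops are dropped with a
    warning; lines with a single column raise :class:`FormatError`."""
    path = Path(path)
    nodes: set[str] = set(extra_nodes)
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) == 1:
                raise FormatError(f"{path.name}:{lineno}: expected 2 or 3 columns, got 1")
            if len(parts) == 2:
                parent, child = parts
            else:  # SIF: parent relation child [child ...]
                parent, children = parts[0], parts[2:]
                for child in children:
                    if parent == child:
                        warnings.warn(f"{path.name}:{lineno}: self-loop {parent} dropped")
                        continue
                    nodes.update((parent, child))
                    edges.add((parent, child))
                continue
            if parent == child:
                warnings.warn(f"{path.name}:{lineno}: self-loop {parent} dropped")
                nodes.add(parent)
                continue
            nodes.update((parent, child))
            edges.add((parent, child))
    return PriorNetwork(nodes=nodes, edges=edges)


def write_network_outputs(
    networks: Mapping[Context, pd.DataFrame],
    cdms: Mapping[str, pd.DataFrame],
    path: str | Path,
    config: Mapping[str, object] | None = None,
) -> None:
    """Write per-context edge tables, CDM tables and a run manifest.

    Edge tables (``edges_<context>.csv``) have columns parent, child,
    probability, sorted descending by probability (Cytoscape-loadable).
    CDM tables (``cdm_<regime>.tsv``) are phosphoprotein x context with
    entries in {-1, 0, +1}.  The manifest echoes every configuration value.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    for ctx, prob in networks.items():
        rows = []
        for child in prob.index:
            for parent in prob.columns:
                if parent == child:
                    continue
                rows.append((parent, child, float(prob.loc[child, parent])))
        table = pd.DataFrame(rows, columns=["parent", "child", "probability"])
        table = table.sort_values(
            ["probability", "parent", "child"], ascending=[False, True, True]
        )
        table.to_csv(outdir / f"edges_{ctx}.csv", index=False)
    for regime_id, cdm in cdms.items():
        out = cdm.copy()
        out.to_csv(outdir / f"cdm_{regime_id}.tsv", sep="\t")
    manifest = {"config": dict(config or {}), "timestamp": pd.Timestamp.now().isoformat()}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    """Read a flat YAML key/value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
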