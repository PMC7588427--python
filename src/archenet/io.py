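"""Readers/writers, pipeline configuration and end-to-end orchestration."""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import annotation, kernel, layout, multilevel, network, pruning
from .annotation import MarkerSet
from .kernel import ExpressionMatrix

__all__ = [
    "PipelineConfig",
    "read_expression",
    "read_markers",
    "save_bundle",
    "load_bundle",
    "run_pipeline",
]

log = logging.getLogger("archenet")


@dataclass
class ReductionConfig:
    D: int = 50
    seed: int = 0
    z_limit: float = 10.0
    n_oversamples: int = 10
    n_iter: int = 5


@dataclass
class DecompositionConfig:
    k_min: int = 2
    k_max: int = 30
    tol: float = 1e-6
    max_iter: int = 100
    nonzero_threshold: float = 1e-5


@dataclass
class NetworkConfig:
    kappa: float = 1.0
    n_candidates: int | None = None


@dataclass
class PruningConfig:
    sig_threshold: float = 0.01
    leiden_resolution: float = 8.0


@dataclass
class LayoutConfig:
    compactness: int = 50
    epochs: int = 500
    seed: int = 0


@dataclass
class AnnotationConfig:
    alpha: float = 0.15
    n_perm: int = 1000
    ratio_threshold: float = 2.0


@dataclass
class PipelineConfig:
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    pruning: PruningConfig = field(default_factory=PruningConfig)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {
            "reduction": ReductionConfig,
            "decomposition": DecompositionConfig,
            "network": NetworkConfig,
            "pruning": PruningConfig,
            "layout": LayoutConfig,
            "annotation": AnnotationConfig,
        }
        kwargs = {}
        for name, typ in sections.items():
            kwargs[name] = typ(**d.get(name, {}))
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "PipelineConfig":
        d = self.to_dict()
        d["reduction"]["seed"] = seed
        d["layout"]["seed"] = seed
        return PipelineConfig.from_dict(d)


def read_expression(path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes x cells matrix.

    Matrix Market (``.mtx``) expects sidecar name files next to the matrix:
    ``<stem>.genes.txt`` and ``<stem>.cells.txt`` (one name per line, genes
    in rows). CSV/TSV expects gene names in the first column and cell names
    in the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or (
        "mtx" if path.suffix == ".mtx" else "tsv" if path.suffix in (".tsv", ".txt") else "csv"
    )
    if fmt == "mtx":
        try:
            M = scipy.io.mmread(path)
        except Exception as exc:
            raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
        genes_f = path.with_suffix("").with_suffix(".genes.txt")
        cells_f = path.with_suffix("").with_suffix(".cells.txt")
        if not genes_f.exists() or not cells_f.exists():
            raise FileNotFoundError(
                f"expected sidecar name files {genes_f.name} and {cells_f.name}"
            )
        gene_names = genes_f.read_text().split()
        cell_names = cells_f.read_text().split()
        return ExpressionMatrix(sp.csc_matrix(M), gene_names, cell_names)
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(g) for g in df.index], [str(c) for c in df.columns]
    )


def read_markers(path) -> list[MarkerSet]:
    """Read marker sets from GMT; a trailing ``-`` marks a negative marker.

    Format per line: ``name<TAB>description<TAB>gene1<TAB>gene2-...``; empty
    lines are skipped. A gene listed with both signs raises a validation
    error (via the MarkerSet invariant).
    """
    sets: list[MarkerSet] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT lines need name, description, >=1 gene")
        name = parts[0]
        pos, neg = [], []
        for tok in parts[2:]:
            tok = tok.strip()
            if not tok:
                continue
            if tok.endswith("-"):
                neg.append(tok[:-1])
            else:
                pos.append(tok)
        sets.append(MarkerSet(name=name, positive=pos, negative=neg))
    return sets


def _write_sparse(grp: h5py.Group, name: str, M: sp.csr_matrix) -> None:
    g = grp.create_group(name)
    g.attrs["shape"] = M.shape
    g.create_dataset("data", data=M.data)
    g.create_dataset("indices", data=M.indices)
    g.create_dataset("indptr", data=M.indptr)


def _read_sparse(grp: h5py.Group) -> sp.csr_matrix:
    return sp.csr_matrix(
        (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
        shape=tuple(grp.attrs["shape"]),
    )


def save_bundle(path, results: dict) -> None:
    """Serialize pipeline results (reduced profile, multilevel factors,
    network, states, embedding, colors) into one HDF5 container."""
    with h5py.File(path, "w") as f:
        red = results["reduced"]
        g = f.create_group("reduced")
        g.create_dataset("S_r", data=red.S_r)
        g.create_dataset("singular_values", data=red.singular_values)
        g.create_dataset("gene_loadings", data=red.gene_loadings)
        g.create_dataset("cell_names", data=np.array(red.cell_names, dtype="S"))

        ml = results["multilevel"]
        g = f.create_group("multilevel")
        g.create_dataset("C_star", data=ml.C_star)
        g.create_dataset("H_star", data=ml.H_star)
        g.create_dataset("W_star", data=ml.W_star)
        g.create_dataset("level_of", data=np.array(ml.level_of))

        net = results["network"]
        g = f.create_group("network")
        _write_sparse(g, "weights", net.weights.tocsr())
        _write_sparse(g, "distances", net.distances.tocsr())
        g.attrs["kappa"] = net.kappa
        g.create_dataset("neighbor_counts", data=net.neighbor_counts)

        st = results["states"]
        g = f.create_group("states")
        g.create_dataset("W_mr", data=st.W_mr)
        g.create_dataset("H_mr", data=st.H_mr)
        g.create_dataset("C_mr", data=st.C_mr)
        g.create_dataset("selected", data=np.array(st.selected))
        g.create_dataset("dominance", data=st.dominance)

        if "embedding" in results:
            emb = results["embedding"]
            g = f.create_group("embedding")
            g.create_dataset("coords", data=emb.coords)
            g.attrs.update(a=emb.a, b=emb.b, compactness=emb.compactness, seed=emb.seed)
        if "embedding3d" in results:
            f.create_dataset("embedding3d/coords", data=results["embedding3d"].coords)
        if "colors" in results:
            f.create_dataset("colors", data=results["colors"])
        if "config" in results:
            f.attrs["config"] = yaml.safe_dump(results["config"].to_dict())


def load_bundle(path) -> dict:
    """Load the HDF5 results container written by :func:`save_bundle`."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        out["reduced"] = dict(
            S_r=f["reduced/S_r"][:],
            singular_values=f["reduced/singular_values"][:],
            gene_loadings=f["reduced/gene_loadings"][:],
            cell_names=[s.decode() for s in f["reduced/cell_names"][:]],
        )
        out["multilevel"] = dict(
            C_star=f["multilevel/C_star"][:],
            H_star=f["multilevel/H_star"][:],
            W_star=f["multilevel/W_star"][:],
            level_of=[tuple(x) for x in f["multilevel/level_of"][:]],
        )
        out["network"] = dict(
            weights=_read_sparse(f["network/weights"]),
            distances=_read_sparse(f["network/distances"]),
            kappa=float(f["network"].attrs["kappa"]),
            neighbor_counts=f["network/neighbor_counts"][:],
        )
        out["states"] = dict(
            W_mr=f["states/W_mr"][:],
            H_mr=f["states/H_mr"][:],
            C_mr=f["states/C_mr"][:],
            selected=[tuple(x) for x in f["states/selected"][:]],
            dominance=f["states/dominance"][:],
        )
        if "embedding" in f:
            out["embedding"] = dict(
                coords=f["embedding/coords"][:], **dict(f["embedding"].attrs)
            )
        if "embedding3d" in f:
            out["embedding3d"] = dict(coords=f["embedding3d/coords"][:])
        if "colors" in f:
            out["colors"] = f["colors"][:]
        if "config" in f.attrs:
            out["config"] = PipelineConfig.from_dict(yaml.safe_load(f.attrs["config"]))
    return out


def run_pipeline(
    config: PipelineConfig,
    expr: ExpressionMatrix,
    markers: list[MarkerSet] | None = None,
    with_layout: bool = True,
) -> dict:
    """Full analysis: reduce -> multilevel -> network -> prune -> layout/colors
    -> optional marker annotation. Returns the results dict (save with
    :func:`save_bundle`); logs per-stage timings at INFO level."""
    results: dict = {"config": config}

    def stage(name, fn):
        t0 = time.perf_counter()
        out = fn()
        log.info("%s: %.2fs", name, time.perf_counter() - t0)
        return out

    rc, dc = config.reduction, config.decomposition
    Z = stage("transform", lambda: kernel.action_kernel_transform(expr, z_limit=rc.z_limit))
    red = stage(
        "reduce",
        lambda: kernel.reduce(
            Z, D=rc.D, seed=rc.seed, n_oversamples=rc.n_oversamples, n_iter=rc.n_iter
        ),
    )
    results["reduced"] = red
    ml = stage(
        "multilevel",
        lambda: multilevel.run_multilevel(
            red, k_min=dc.k_min, k_max=dc.k_max, max_iter=dc.max_iter, tol=dc.tol
        ),
    )
    results["multilevel"] = ml
    H_norm = network.normalize_encodings(ml.H_star)
    net = stage(
        "network",
        lambda: network.build_network(
            H_norm,
            kappa=config.network.kappa,
            cell_names=red.cell_names,
            n_candidates=config.network.n_candidates,
        ),
    )
    results["network"] = net
    states = stage(
        "prune",
        lambda: pruning.prune(
            ml,
            sig_threshold=config.pruning.sig_threshold,
            leiden_resolution=config.pruning.leiden_resolution,
            seed=rc.seed,
            threshold=dc.nonzero_threshold,
        ),
    )
    results["states"] = states
    if with_layout:
        lc = config.layout
        results["embedding"] = stage(
            "layout2d",
            lambda: layout.embed(net, dims=2, compactness=lc.compactness,
                                 epochs=lc.epochs, seed=lc.seed),
        )
        emb3 = stage(
            "layout3d",
            lambda: layout.embed(net, dims=3, compactness=lc.compactness,
                                 epochs=lc.epochs, seed=lc.seed),
        )
        results["embedding3d"] = emb3
        results["colors"] = layout.denovo_colors(emb3)
    if markers:
        ac = config.annotation
        results["annotation"] = stage(
            "annotate",
            lambda: annotation.annotate_cells(
                expr, net, markers, n_perm=ac.n_perm, seed=rc.seed, alpha=ac.alpha
            ),
        )
    return results
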