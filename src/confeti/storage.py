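"""HDF5/JSON persistence for decompositions, covariances and flag results."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .datatypes import ComponentFlagResult, IcaDecomposition, SampleCovariance

__all__ = [
    "save_decomposition",
    "load_decomposition",
    "save_covariance",
    "load_covariance",
    "save_flags",
    "load_flags",
]


def save_decomposition(D: IcaDecomposition, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("/A", data=D.A)
        fh.create_dataset("/S", data=D.S)
        fh.create_dataset("/center", data=D.center)
        fh.create_dataset("/sample_ids", data=[str(s).encode() for s in D.sample_ids])
        fh.create_dataset("/gene_ids", data=[str(g).encode() for g in D.gene_ids])
        meta = fh.create_group("/meta")
        meta.attrs["k"] = D.k
        meta.attrs["seed"] = D.seed
        meta.attrs["converged"] = D.converged
        meta.attrs["n_iter"] = D.n_iter


def load_decomposition(path: str) -> IcaDecomposition:
    with h5py.File(path, "r") as fh:
        meta = fh["/meta"].attrs
        return IcaDecomposition(
            A=fh["/A"][()],
            S=fh["/S"][()],
            center=fh["/center"][()],
            k=int(meta["k"]),
            seed=int(meta["seed"]),
            converged=bool(meta["converged"]),
            n_iter=int(meta["n_iter"]),
            sample_ids=pd.Index([s.decode() for s in fh["/sample_ids"][()]]),
            gene_ids=pd.Index([g.decode() for g in fh["/gene_ids"][()]]),
        )


def save_covariance(K: SampleCovariance, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("/K", data=K.K)
        fh.create_dataset("/eigenvalues", data=K.eigenvalues)
        fh.create_dataset("/eigenvectors", data=K.eigenvectors)
        fh.create_dataset("/sample_ids", data=[str(s).encode() for s in K.sample_ids])
        fh.attrs["method"] = K.method
        fh.attrs["provenance"] = json.dumps(K.provenance, default=str)


def load_covariance(path: str) -> SampleCovariance:
    with h5py.File(path, "r") as fh:
        return SampleCovariance(
            K=fh["/K"][()],
            method=str(fh.attrs["method"]),
            sample_ids=pd.Index([s.decode() for s in fh["/sample_ids"][()]]),
            provenance=json.loads(fh.attrs.get("provenance", "{}")),
        )


def save_flags(flags: ComponentFlagResult, path: str) -> None:
    payload = {
        "min_p": [float(x) for x in flags.min_p],
        "best_snp": [str(s) for s in flags.best_snp],
        "flagged": sorted(int(j) for j in flags.flagged),
        "alpha": flags.alpha,
        "n_tests": flags.n_tests,
        "genotype_subset": sorted(flags.genotype_subset)
        if flags.genotype_subset is not None
        else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_flags(path: str) -> ComponentFlagResult:
    with open(path) as fh:
        payload = json.load(fh)
    return ComponentFlagResult(
        min_p=np.asarray(payload["min_p"], dtype=float),
        best_snp=payload["best_snp"],
        flagged=set(payload["flagged"]),
        alpha=payload["alpha"],
        n_tests=payload["n_tests"],
        genotype_subset=set(payload["genotype_subset"])
        if payload["genotype_subset"] is not None
        else None,
    )
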