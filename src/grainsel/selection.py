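"""Ranking lines by breeding value and expected response to selection.

Response to selection follows the breeder's equation in its truncated form:
selecting the k best lines as parents, the expected phenotypic gain is

    R = (P_top - P_mean) * h2,

where P_top is the mean phenotype of the selected lines, P_mean the
population mean phenotype and h2 the trait heritability.  On the breeding-
value scale the response is simply mean BV(selected) - mean BV(population):
BVs are already genetic values, so no further h2 weighting applies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import PhenotypeTable
from .mixed_model import BreedingValues, VarianceComponents

__all__ = ["SelectionReport", "rank_by_bv", "response_to_selection"]


@dataclass
class SelectionReport:
    trait: str
    mode: str  # "by_bv" | "by_phenotype"
    k: int
    top_ids: list
    bv_response: float  # mean BV(top) - mean BV(all), trait units
    pheno_response: float  # (Ptop - Pmean) * h2, trait units
    h2: float
    p_top: float
    p_mean: float

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def rank_by_bv(bv: BreedingValues, k: int = 30) -> list:
    """Ids of the k lines with the largest estimated BV.

    Ties at the cutoff are broken by position in the sample-ID order (the
    earlier line wins), so the result is deterministic.
    """
    n = len(bv.sample_ids)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds population size {n}")
    order = np.argsort(-np.asarray(bv.bv), kind="stable")
    return list(bv.sample_ids[order[:k]])


def _top_by_values(ids: np.ndarray, values: np.ndarray, k: int) -> list:
    order = np.argsort(-values, kind="stable")
    return list(ids[order[:k]])


def response_to_selection(
    bv: BreedingValues,
    phenos: PhenotypeTable,
    vc: VarianceComponents,
    trait: str,
    k: int = 30,
    mode: str = "by_bv",
) -> SelectionReport:
    """Expected response from selecting the top-k lines of one trait.

    ``mode="by_bv"`` selects on estimated breeding value (the genomic-
    selection scenario); ``mode="by_phenotype"`` selects on the observed
    line mean (conventional phenotypic selection).  Both the BV-scale and
    the breeder's-equation phenotype-scale responses are reported.
    """
    if mode not in ("by_bv", "by_phenotype"):
        raise ValueError(f"unknown mode {mode!r}")
    means = phenos.line_means(trait, sample_ids=bv.sample_ids)
    ids = np.asarray(bv.sample_ids, dtype=object)
    if len(means) != len(ids):
        missing = sorted(set(map(str, ids)) - set(means.index))
        raise ValueError(f"lines without {trait!r} phenotype: {missing[:10]}")
    pheno = means.to_numpy(dtype=float)
    bvals = np.asarray(bv.bv, dtype=float)

    if mode == "by_bv":
        top = rank_by_bv(bv, k=k)
    else:
        top = _top_by_values(ids, pheno, k)
    pos = {s: i for i, s in enumerate(ids)}
    sel = np.array([pos[s] for s in top])

    p_top = float(pheno[sel].mean())
    p_mean = float(pheno.mean())
    bv_resp = float(bvals[sel].mean() - bvals.mean())
    pheno_resp = (p_top - p_mean) * vc.h2
    return SelectionReport(
        trait=trait,
        mode=mode,
        k=k,
        top_ids=top,
        bv_response=bv_resp,
        pheno_response=float(pheno_resp),
        h2=float(vc.h2),
        p_top=p_top,
        p_mean=p_mean,
    )
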