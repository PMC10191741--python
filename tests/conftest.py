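"""Shared fixtures: small genotype matrices, climate tables, builders."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from pial.dataio import GenotypeMatrix

logging.disable(logging.WARNING)


def make_genotype_matrix(pop_calls: list[list[float]], locus_ids=None) -> GenotypeMatrix:
    """One-locus-per-column matrix from per-population genotype lists.

    ``pop_calls[s]`` is a list of per-individual call tuples (or scalars
    for a single locus) for population s.
    """
    rows, ind_rows = [], []
    for s, pc in enumerate(pop_calls):
        for i, g in enumerate(pc):
            rows.append([float(x) for x in (g if hasattr(g, "__len__") else [g])])
            ind_rows.append((f"P{s}I{i}", f"P{s}"))
    calls = np.array(rows, dtype=float)
    n_loci = calls.shape[1]
    if locus_ids is None:
        locus_ids = [f"L{j + 1}_1" for j in range(n_loci)]
    individuals = pd.DataFrame(ind_rows, columns=["individual_id", "site_id"])
    sites = pd.DataFrame(
        {
            "site_id": [f"P{s}" for s in range(len(pop_calls))],
            "utm_e": np.linspace(0, 1e4, len(pop_calls)),
            "utm_n": np.linspace(0, 1e5, len(pop_calls)),
            "latitude": np.linspace(39, 36, len(pop_calls)),
        }
    )
    loci = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "parent_locus": [l.rsplit("_", 1)[0] for l in locus_ids],
            "position": [int(l.rsplit("_", 1)[1]) if "_" in l else 1 for l in locus_ids],
        }
    )
    return GenotypeMatrix(calls=calls, individuals=individuals, loci=loci, sites=sites)


def wc_theta_oracle(pops: list[list[int]]) -> float:
    """Scalar Weir & Cockerham (1984) theta for one biallelic locus.

    Independent of the package implementation: direct transcription of
    the variance-component formulas for r populations, with ``pops``
    holding per-individual minor-allele counts.
    """
    r = len(pops)
    n_i = np.array([len(p) for p in pops], dtype=float)
    p_i = np.array([np.sum(p) / (2 * len(p)) for p in pops])
    h_i = np.array([np.mean(np.asarray(p) == 1) for p in pops])
    nbar = n_i.mean()
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
    pbar = np.sum(n_i * p_i) / (r * nbar)
    s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
    hbar = np.sum(n_i * h_i) / (r * nbar)
    a = nbar / nc * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a / (a + b + c))


def island_model_matrix(
    rng: np.random.Generator,
    fst: float,
    n_sites: int = 6,
    n_ind: int = 10,
    n_loci: int = 150,
) -> GenotypeMatrix:
    """Balding-Nichols island-model genotypes at a target FST level."""
    p0 = rng.uniform(0.1, 0.9, n_loci)
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    p = rng.beta(np.tile(a, (n_sites, 1)), np.tile(b, (n_sites, 1)))
    site_of = np.repeat(np.arange(n_sites), n_ind)
    calls = rng.binomial(2, p[site_of, :]).astype(float)
    return make_genotype_matrix(
        [calls[site_of == s].tolist() for s in range(n_sites)]
    )


@pytest.fixture
def monthly_climate() -> pd.DataFrame:
    """Two water years of monthly data for one site, simple integers."""
    rows = []
    for wy in (2000, 2001):
        months = [(wy - 1, m) for m in (10, 11, 12)] + [(wy, m) for m in range(1, 10)]
        for k, (yr, mo) in enumerate(months):
            rows.append(
                {
                    "site_id": "S01",
                    "year": yr,
                    "month": mo,
                    "PPT": 10.0,
                    "Tmn": float(k - 5),
                    "Tmx": float(k + 7),
                    "PET": 50.0,
                    "AET": 40.0,
                    "CWD": 10.0,
                }
            )
    return pd.DataFrame(rows)
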