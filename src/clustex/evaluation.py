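"""Evaluation of identified modules against reference responsive gene sets.

Sensitivity is the fraction of the reference set covered by the module.
The signal-to-noise ratio compares the observed module/reference overlap
(signal) with the mean overlap of same-size control gene sets sampled
uniformly from the complete gene list (noise; 10,000 control sets by
default).  The complete gene list defaults to the network ∩ expression
universe; reference and module genes outside it are dropped (with a
warning for the module side) before computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass
class EvaluationReport:
    reference_name: str
    sensitivity: float
    observed_overlap: int
    noise_mean: float
    s_over_n: float
    module_size: int
    reference_size: int
    universe_size: int
    n_controls: int
    seed: int


def sensitivity(module_genes: frozenset[str] | set[str], reference: frozenset[str] | set[str]) -> float:
    """|module ∩ reference| / |reference|."""
    if not reference:
        raise ConfigurationError("reference gene set is empty")
    return len(set(module_genes) & set(reference)) / len(reference)


def signal_to_noise(
    module_genes: frozenset[str] | set[str],
    reference: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    n_controls: int = 10000,
    seed: int = 0,
    reference_name: str = "reference",
) -> EvaluationReport:
    """S/N of the module/reference overlap against uniform same-size controls.

    Controls are sampled without replacement within each set; the noise is
    the mean control/reference overlap (its expectation is the
    hypergeometric |module| * |reference| / |universe|).
    """
    universe_list = sorted(set(universe))
    if not universe_list:
        raise ConfigurationError("universe is empty")
    module_in = set(module_genes) & set(universe_list)
    dropped = len(set(module_genes)) - len(module_in)
    if dropped:
        warnings.warn(f"{dropped} module genes outside the universe were dropped")
    reference_in = set(reference) & set(universe_list)
    if not reference_in:
        raise ConfigurationError("reference has no genes in the universe")
    if not module_in:
        raise ConfigurationError("module has no genes in the universe")
    m = len(module_in)
    if m > len(universe_list):
        raise ConfigurationError("module larger than universe")

    signal = len(module_in & reference_in)
    is_ref = np.array([g in reference_in for g in universe_list], dtype=float)

    rng = np.random.default_rng(seed)
    pool = len(universe_list)
    overlaps = np.empty(n_controls)
    chunk = max(1, int(2e7) // pool)
    for start in range(0, n_controls, chunk):
        stop = min(start + chunk, n_controls)
        u = rng.random((stop - start, pool))
        if m < pool:
            picks = np.argpartition(u, m, axis=1)[:, :m]
            overlaps[start:stop] = is_ref[picks].sum(axis=1)
        else:
            overlaps[start:stop] = is_ref.sum()
    noise_mean = float(overlaps.mean())
    if noise_mean == 0.0:
        raise ConfigurationError("noise mean is zero; S/N undefined")
    return EvaluationReport(
        reference_name=reference_name,
        sensitivity=signal / len(reference_in),
        observed_overlap=int(signal),
        noise_mean=noise_mean,
        s_over_n=signal / noise_mean,
        module_size=m,
        reference_size=len(reference_in),
        universe_size=pool,
        n_controls=n_controls,
        seed=seed,
    )


def write_evaluation(reports: list[EvaluationReport], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "reference\tsensitivity\tobserved_overlap\tnoise_mean\ts_over_n\t"
            "module_size\treference_size\tuniverse_size\tn_controls\tseed\n"
        )
        for r in reports:
            fh.write(
                f"{r.reference_name}\t{r.sensitivity:.6g}\t{r.observed_overlap}\t"
                f"{r.noise_mean:.6g}\t{r.s_over_n:.6g}\t{r.module_size}\t"
                f"{r.reference_size}\t{r.universe_size}\t{r.n_controls}\t{r.seed}\n"
            )
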