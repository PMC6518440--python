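"""Panel-by-region triplex screening and universal-TTS classification.

The screen scores every (RNA, region) pair: the engine counts qualifying
windows (N_tpx), the calibration model supplies the length-dependent
Poisson mean, and the exact Poisson upper tail gives a p-value that is
Bonferroni-adjusted within the configured family (default: per RNA, one
family per transcript's scan over all regions).  A region significant
(adjusted p < alpha, strict) for more than ``universal_fraction`` (strict
>, default 0.9) of the transcript panel is called a universal triplex
target site.

Two entry styles are provided: plain functions (:func:`scan_matrix`,
:func:`classify_universal`, ...) operating on DataFrames, and a
statsmodels-style pair :class:`TriplexScreen` / :class:`TriplexScreenResults`
wrapping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import EngineParams, count_triplexes
from .io import GenomicRegion, NucleicSequence, extract_region_sequence
from .significance import (CalibrationModel, bonferroni_adjust,
                           expected_lambda, triplex_pvalue)

__all__ = [
    "scan_matrix",
    "classify_universal",
    "summarize_per_rna",
    "export_matrix",
    "TriplexScreen",
    "TriplexScreenResults",
]

RegionInput = (
    "NucleicSequence | tuple[GenomicRegion, NucleicSequence]"
)


def _normalize_regions(regions) -> list[tuple[str, NucleicSequence]]:
    out = []
    for item in regions:
        if isinstance(item, NucleicSequence):
            out.append((item.id, item))
        else:
            region, seq = item
            out.append((region.label, seq))
    return out


def scan_matrix(rnas: Sequence[NucleicSequence],
                regions,
                model: CalibrationModel | None = None,
                params: EngineParams | None = None,
                alpha: float = 0.01,
                family: str = "per-rna") -> pd.DataFrame:
    """Score every RNA x region pair.

    Parameters
    ----------
    regions
        Either ``NucleicSequence`` objects (pre-extracted region sequences)
        or ``(GenomicRegion, NucleicSequence)`` tuples; both paths produce
        identical downstream results.
    family : {"per-rna", "global"}
        Bonferroni family: the number of regions tested per RNA (each
        transcript's scan is one family), or all RNA x region tests.

    Returns
    -------
    DataFrame with one row per pair: rna_id, region, L_RNA, L_DNA, n_tpx,
    lam, p, adj_p, significant.
    """
    model = model or CalibrationModel.default()
    params = params or EngineParams()
    rnas = list(rnas)
    named = _normalize_regions(regions)
    if not rnas or not named:
        raise ValueError("RNA panel and region set must be non-empty")
    if family not in ("per-rna", "global"):
        raise ValueError("family must be 'per-rna' or 'global'")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    m = len(named) if family == "per-rna" else len(named) * len(rnas)
    rows = []
    for rna in rnas:
        for label, seq in named:
            n_tpx = count_triplexes(rna, seq, params)
            lam = expected_lambda(model, len(rna), len(seq))
            p = triplex_pvalue(n_tpx, lam)
            adj_p = bonferroni_adjust(p, m)
            rows.append((rna.id, label, len(rna), len(seq), n_tpx, lam, p,
                         adj_p, adj_p < alpha))
    return pd.DataFrame(rows, columns=[
        "rna_id", "region", "L_RNA", "L_DNA", "n_tpx", "lam", "p", "adj_p",
        "significant"])


def classify_universal(results: pd.DataFrame,
                       universal_fraction: float = 0.9) -> pd.DataFrame:
    """Per-region fraction of the panel significant, and the universal call.

    A region is universal iff its fraction strictly exceeds
    ``universal_fraction`` (the "more than 90% of transcripts" rule).
    """
    if results is None or len(results) == 0:
        raise ValueError("no interaction results to classify")
    panels = results.groupby("region")["rna_id"].agg(frozenset)
    if panels.nunique() != 1:
        raise ValueError("inconsistent RNA panel across regions")
    grp = results.groupby("region", sort=True)["significant"]
    out = grp.agg(n_rnas_tested="size", n_significant="sum").reset_index()
    out["fraction"] = out["n_significant"] / out["n_rnas_tested"]
    out["is_universal"] = out["fraction"] > universal_fraction
    return out


def summarize_per_rna(results: pd.DataFrame) -> pd.DataFrame:
    """Per RNA: number and fraction of regions with a significant call."""
    if results is None or len(results) == 0:
        raise ValueError("no interaction results to summarise")
    grp = results.groupby("rna_id", sort=True)["significant"]
    out = grp.agg(n_regions="size", n_significant="sum").reset_index()
    out["fraction"] = out["n_significant"] / out["n_regions"]
    return out


def export_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Regions x RNAs matrix of -log10(adjusted p); adj_p = 1 maps to 0.

    Adjusted p-values that underflowed to exactly 0 are floored at the
    smallest positive double (entries ~308) to keep the matrix finite.
    """
    if results is None or len(results) == 0:
        raise ValueError("no interaction results to export")
    counts = results.groupby(["region", "rna_id"]).size()
    if (counts != 1).any():
        raise ValueError("duplicate RNA x region entries")
    mat = results.pivot(index="region", columns="rna_id", values="adj_p")
    if mat.isna().any().any():
        raise ValueError("incomplete RNA x region grid")
    tiny = np.finfo(float).tiny
    return -np.log10(mat.clip(lower=tiny))


@dataclass
class TriplexScreen:
    """Model object: an RNA panel screened against a set of DNA regions.

    Parameters
    ----------
    rnas
        Transcript panel.
    regions
        Region sequences, or ``(GenomicRegion, NucleicSequence)`` tuples.
    params, calibration
        Engine thresholds and the lambda calibration (defaults: canonical
        ``-l 10 -e 10`` search and the shipped reference calibration).
    alpha
        Significance level on the Bonferroni-adjusted p (strict <).
    family : {"per-rna", "global"}
        Bonferroni family definition.
    """

    rnas: Sequence[NucleicSequence]
    regions: Sequence
    params: EngineParams = field(default_factory=EngineParams)
    calibration: CalibrationModel = field(
        default_factory=CalibrationModel.default)
    alpha: float = 0.01
    family: str = "per-rna"

    @classmethod
    def from_bed(cls, rnas, bed_regions: Sequence[GenomicRegion],
                 genome: Sequence[NucleicSequence], **kwargs) -> "TriplexScreen":
        """Build a screen from BED regions plus a genome record set."""
        genome_map = {s.id: s for s in genome}
        regions = [(r, extract_region_sequence(genome_map, r))
                   for r in bed_regions]
        return cls(rnas=rnas, regions=regions, **kwargs)

    def fit(self) -> "TriplexScreenResults":
        interactions = scan_matrix(self.rnas, self.regions,
                                   model=self.calibration, params=self.params,
                                   alpha=self.alpha, family=self.family)
        return TriplexScreenResults(model=self, interactions=interactions)


@dataclass
class TriplexScreenResults:
    """Fitted screen: the interaction table plus derived summaries."""

    model: TriplexScreen
    interactions: pd.DataFrame

    def universal_calls(self, universal_fraction: float = 0.9) -> pd.DataFrame:
        return classify_universal(self.interactions, universal_fraction)

    def per_rna_summary(self) -> pd.DataFrame:
        return summarize_per_rna(self.interactions)

    def neglog10_matrix(self) -> pd.DataFrame:
        return export_matrix(self.interactions)

    def summary(self, universal_fraction: float = 0.9) -> str:
        calls = self.universal_calls(universal_fraction)
        per_rna = self.per_rna_summary()
        n_regions = len(calls)
        n_universal = int(calls["is_universal"].sum())
        frac_sig = self.interactions["significant"].mean()
        lines = [
            "Triplex screen summary",
            "======================",
            f"RNAs: {per_rna.shape[0]}   regions: {n_regions}   "
            f"pairs: {len(self.interactions)}",
            f"engine: min_length={self.model.params.min_length} "
            f"max_error_rate={self.model.params.max_error_rate}%",
            f"calibration: theta=({self.model.calibration.theta0:.4g}, "
            f"{self.model.calibration.theta1:.4g}, "
            f"{self.model.calibration.theta2:.4g}) "
            f"[{self.model.calibration.provenance}]",
            f"alpha={self.model.alpha} (Bonferroni, family={self.model.family})",
            f"significant pairs: {int(self.interactions['significant'].sum())} "
            f"({100 * frac_sig:.1f}%)",
            f"universal TTSs (> {100 * universal_fraction:.0f}% of panel): "
            f"{n_universal} of {n_regions} "
            f"({100 * n_universal / n_regions:.1f}%)",
        ]
        return "\n".join(lines)

    def to_tsv(self, out_dir: str | Path,
               universal_fraction: float = 0.9) -> None:
        """Write interactions, universal calls, per-RNA summary and matrix."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.interactions.to_csv(out / "interactions.tsv", sep="\t", index=False)
        self.universal_calls(universal_fraction).to_csv(
            out / "universal_calls.tsv", sep="\t", index=False)
        self.per_rna_summary().to_csv(
            out / "per_rna_summary.tsv", sep="\t", index=False)
        self.neglog10_matrix().to_csv(out / "matrix.tsv", sep="\t")
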