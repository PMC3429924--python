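"""Model/Results interface over the mosaic statistics.

``CloneFrequencyModel`` is built from clone-level data (a tidy DataFrame,
called wings, or transcribed class counts) and ``fit()`` returns a
``CloneFrequencyResults`` carrying per-group summaries, bootstrap
uncertainty for the induction frequency, goodness-of-fit diagnostics
(Poisson clone counts per wing, halve-by-half class decay), and a
``summary()`` table mirroring the published layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .records import WingRecord
from .stats import (
    HalveByHalfExpectation,
    LossRateEstimate,
    MosaicSummary,
    PoissonFitResult,
    compare_frequencies,
    halve_by_half_expected,
    poisson_expected,
    recover_loss_rate,
    summarize_group,
)

__all__ = ["CloneFrequencyModel", "CloneFrequencyResults"]


class CloneFrequencyModel:
    """Chromosome-loss frequency model for wing-spot clone data.

    Parameters
    ----------
    clones : pandas.DataFrame
        Tidy clone table with columns ``group``, ``wing_id``, ``size``.
    n_wings : int or mapping group -> int
        Wings screened per group, including clone-free wings (which the
        clone table cannot show).
    screened_cells : int
        C, screened cells per wing (default 30000).
    size_classes : int
        Number of size-class bins reported (default 8).
    m_override : mapping group -> float, optional
        Published average clone sizes to use in place of the
        mean-class-index estimate.
    simulation_config : SimulationConfig, optional
        Generating configuration; when present, ``fit`` additionally
        recovers the mechanistic per-division loss probability by
        inverting the branching-model expectation of f.
    """

    def __init__(
        self,
        clones: pd.DataFrame,
        n_wings: int | Mapping[str, int],
        screened_cells: int = 30000,
        size_classes: int = 8,
        m_override: Mapping[str, float] | None = None,
        simulation_config: SimulationConfig | None = None,
    ) -> None:
        required = {"group", "wing_id", "size"}
        missing = required - set(clones.columns)
        if missing:
            raise ValueError(f"clone table missing columns {sorted(missing)}")
        self.clones = clones.reset_index(drop=True)
        groups = list(dict.fromkeys(self.clones["group"])) or (
            list(n_wings) if isinstance(n_wings, Mapping) else []
        )
        if isinstance(n_wings, Mapping):
            self.n_wings = dict(n_wings)
            for g in groups:
                if g not in self.n_wings:
                    raise ValueError(f"n_wings missing for group {g!r}")
        else:
            if len(groups) > 1:
                raise ValueError("scalar n_wings requires a single group")
            self.n_wings = {g: int(n_wings) for g in (groups or ["all"])}
        self.groups = list(self.n_wings)
        self.screened_cells = int(screened_cells)
        self.size_classes = int(size_classes)
        self.m_override = dict(m_override or {})
        self.simulation_config = simulation_config

    # -- constructors -------------------------------------------------

    @classmethod
    def from_wing_records(
        cls,
        wings: Iterable[WingRecord],
        max_gap: int = 3,
        hinge_mask=None,
        min_trichomes_solo: int = 2,
        screened_cells: int | None = None,
        **kwargs,
    ) -> "CloneFrequencyModel":
        """Score wings with the standard rules and build the model.

        ``screened_cells`` defaults to the observed mean unmasked cell
        count per wing.
        """
        from .calling import call_wing

        wings = list(wings)
        rows = []
        n_wings: dict[str, int] = {}
        c_total = 0
        for wing in wings:
            n_wings[wing.group] = n_wings.get(wing.group, 0) + 1
            c_total += wing.screened_cells
            for call in call_wing(
                wing,
                max_gap=max_gap,
                hinge_mask=hinge_mask,
                min_trichomes_solo=min_trichomes_solo,
            ):
                rows.append(
                    {"group": wing.group, "wing_id": wing.wing_id, "size": call.size}
                )
        if screened_cells is None:
            screened_cells = int(round(c_total / max(len(wings), 1)))
        clones = pd.DataFrame(rows, columns=["group", "wing_id", "size"])
        model = cls(clones, n_wings, screened_cells=screened_cells, **kwargs)
        model._wing_ids = {
            g: [w.wing_id for w in wings if w.group == g] for g in n_wings
        }
        return model

    @classmethod
    def from_class_counts(
        cls,
        class_counts: Sequence[int],
        n_wings: int,
        group: str = "group",
        screened_cells: int = 30000,
        **kwargs,
    ) -> "CloneFrequencyModel":
        """Build from transcribed class counts (one published table row).

        Clone sizes are materialised at the lower edge of each class; only
        class-level statistics are meaningful for such a model.
        """
        sizes: list[int] = []
        for i, count in enumerate(class_counts, start=1):
            low = 1 if i == 1 else 2 ** (i - 2) + 1
            sizes.extend([low] * int(count))
        clones = pd.DataFrame(
            {"group": group, "wing_id": "pooled", "size": sizes},
            columns=["group", "wing_id", "size"],
        )
        model = cls(clones, {group: int(n_wings)}, screened_cells=screened_cells, **kwargs)
        model._class_counts_input = {group: tuple(int(c) for c in class_counts)}
        return model

    # -- fitting ------------------------------------------------------

    def _per_wing_sizes(self, group: str) -> list[list[int]]:
        sub = self.clones[self.clones["group"] == group]
        by_wing: dict[str, list[int]] = {}
        for wid, size in zip(sub["wing_id"], sub["size"]):
            by_wing.setdefault(str(wid), []).append(int(size))
        known = getattr(self, "_wing_ids", {}).get(group)
        if known is not None:
            return [by_wing.get(w, []) for w in known]
        sizes = [by_wing[w] for w in sorted(by_wing)]
        sizes.extend([[]] * (self.n_wings[group] - len(sizes)))
        return sizes

    def fit(
        self,
        n_bootstrap: int = 0,
        confidence: float = 0.95,
        seed: int | None = None,
    ) -> "CloneFrequencyResults":
        """Compute per-group summaries (and bootstrap intervals if asked)."""
        summaries: dict[str, MosaicSummary] = {}
        estimates: dict[str, LossRateEstimate] = {}
        for group in self.groups:
            counts_in = getattr(self, "_class_counts_input", {}).get(group)
            override = self.m_override.get(group)
            if counts_in is not None:
                summaries[group] = summarize_group(
                    class_counts=counts_in,
                    N=self.n_wings[group],
                    C=self.screened_cells,
                    classes=self.size_classes,
                    m_override=override,
                    group=group,
                )
            else:
                sizes = self.clones.loc[self.clones["group"] == group, "size"]
                summaries[group] = summarize_group(
                    sizes.tolist(),
                    N=self.n_wings[group],
                    C=self.screened_cells,
                    classes=self.size_classes,
                    m_override=override,
                    group=group,
                )
            estimates[group] = recover_loss_rate(
                self._per_wing_sizes(group),
                C=self.screened_cells,
                n_bootstrap=n_bootstrap,
                confidence=confidence,
                seed=seed,
                config=self.simulation_config,
                classes=self.size_classes,
            )
        return CloneFrequencyResults(
            model=self, summaries=summaries, estimates=estimates
        )


@dataclass
class CloneFrequencyResults:
    """Fitted per-group mosaic statistics and diagnostics."""

    model: CloneFrequencyModel
    summaries: dict[str, MosaicSummary]
    estimates: dict[str, LossRateEstimate]

    # -- diagnostics ---------------------------------------------------

    def per_wing_counts(self, group: str, i_max: int | None = None) -> list[int]:
        """Observed numbers of wings bearing 0, 1, 2, ... clones."""
        sizes = self.model._per_wing_sizes(group)
        counts = [len(w) for w in sizes]
        top = max(counts, default=0) if i_max is None else i_max
        hist = [0] * (top + 1)
        for c in counts:
            hist[min(c, top)] += 1
        return hist

    def poisson_fit(
        self,
        group: str,
        i_max: int | None = None,
        pool_below: float = 1.0,
        estimate_rate_df: bool = False,
    ) -> PoissonFitResult:
        """Poisson model of per-wing clone counts for one group."""
        s = self.summaries[group]
        observed = self.per_wing_counts(group, i_max)
        return poisson_expected(
            s.n,
            s.N,
            len(observed) - 1,
            observed=observed,
            pool_below=pool_below,
            estimate_rate_df=estimate_rate_df,
        )

    def halve_by_half(
        self, group: str, K: int | None = None, pool_below: float = 1.0
    ) -> tuple[HalveByHalfExpectation, tuple[float, int, float]]:
        """Halve-by-half expectation and its goodness-of-fit for one group."""
        s = self.summaries[group]
        counts = np.asarray(s.class_counts)
        if K is None:
            nonzero = np.flatnonzero(counts)
            K = int(nonzero[-1]) + 1 if len(nonzero) else 1
        exp = halve_by_half_expected(s.n, K)
        observed = counts[:K].tolist()
        observed[-1] += int(counts[K:].sum())  # clones beyond K fold into the tail
        gof = exp.gof(observed, pool_below=pool_below)
        return exp, gof

    def homogeneity(self, groups: Sequence[str] | None = None):
        """Common-rate chi-square across groups (clones per wing)."""
        groups = list(groups) if groups is not None else list(self.summaries)
        pairs = [(self.summaries[g].n, self.summaries[g].N) for g in groups]
        return compare_frequencies(pairs)

    # -- presentation --------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """One row per group in the published table layout."""
        rows = []
        for g, s in self.summaries.items():
            est = self.estimates.get(g)
            row = {
                "group": g,
                "N": s.N,
                "n": s.n,
                "n_per_N": round(s.clones_per_wing, 1),
            }
            for i, c in enumerate(s.class_counts, start=1):
                row[f"class_{i}"] = c
            row["mean_class"] = (
                round(s.mean_class, 2) if math.isfinite(s.mean_class) else math.nan
            )
            row["m"] = s.m
            row["f_per_1e4"] = s.f_per_1e4
            if est is not None and est.f_interval is not None:
                row["f_lo_1e4"] = round(est.f_interval[0] * 1e4, 2)
                row["f_hi_1e4"] = round(est.f_interval[1] * 1e4, 2)
            if est is not None and est.p_loss_hat is not None:
                row["p_loss_hat"] = est.p_loss_hat
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Printable fit report."""
        lines = ["Chromosome-loss clone frequency", "=" * 72]
        frame = self.summary_frame()
        lines.append(frame.to_string(index=False))
        lines.append("")
        lines.append(f"C (screened cells/wing): {self.model.screened_cells}")
        for g, s in self.summaries.items():
            if s.n and math.isfinite(s.m):
                lines.append(
                    f"{g}: f = {s.f_per_1e4} x 1e-4 per cell division; "
                    f"target cells/wing = {s.target_cells:.0f}"
                )
        if len(self.summaries) >= 2:
            stat, df, p = self.homogeneity()
            lines.append(
                f"homogeneity of clone rates: chi2 = {stat:.2f}, df = {df}, p = {p:.3f}"
            )
        return "\n".join(lines)
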