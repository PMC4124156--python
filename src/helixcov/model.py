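"""Model/Results facade for helix-helix interaction inference.

``HelixInteractionModel`` bundles the data (a coupling matrix and a helix
annotation) with the detector configuration; ``fit`` estimates the
strength distributions and the calibration curve(s) from labelled
training data and returns a ``HelixInteractionResults`` carrying the
per-pair predictions, the fitted parameters and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import HelixAnnotation
from .couplings import CouplingMatrix
from .detector import (
    CalibrationModel,
    CombinedCalibration,
    HelixPairPrediction,
    PatternTemplate,
    StrengthDistributions,
    build_pattern_template,
    combine_calibrations,
    fit_calibration,
    fit_strength_distributions,
    predict_all_pairs,
)


class HelixInteractionModel:
    """Helix-helix interaction detector bound to one coupling matrix.

    Parameters
    ----------
    coupling_matrix
        Symmetric L x L coupling strengths with reference numbering.
    annotation
        Helix/loop segmentation over the same numbering.
    template
        Pattern template; the default is the 17 x 17 cosine-ridge pattern
        with 3.5-residue periodicity.
    prior
        Prior probability that a helix pair interacts.
    aggregation
        Aggregation over pattern positions (``max`` or ``logsumexp``).
    """

    def __init__(
        self,
        coupling_matrix: CouplingMatrix,
        annotation: HelixAnnotation,
        template: PatternTemplate | None = None,
        prior: float = 0.3,
        aggregation: str = "max",
    ):
        self.coupling_matrix = coupling_matrix
        self.annotation = annotation
        self.template = template or build_pattern_template()
        self.prior = prior
        self.aggregation = aggregation

    def _training_strengths(
        self, labelled_pairs: Sequence[tuple[np.ndarray, bool]]
    ) -> list[tuple[float, bool]]:
        """Cell-level labelled strengths from labelled helix-pair blocks.

        Cells of interacting blocks that sit on the stripe (top decile)
        approximate interacting residue pairs; non-interacting blocks
        contribute background cells.
        """
        out: list[tuple[float, bool]] = []
        for block, label in labelled_pairs:
            block = np.asarray(block, dtype=float)
            if label:
                cut = np.quantile(block, 0.9)
                for v in block[block >= cut].ravel():
                    out.append((float(v), True))
            else:
                for v in block.ravel():
                    out.append((float(v), False))
        return out

    def fit(
        self,
        distribution_pairs: Sequence[tuple[np.ndarray, bool]],
        calibration_sets: Sequence[Sequence[tuple[np.ndarray, bool]]] = (),
        bin_size: int = 60,
    ) -> "HelixInteractionResults":
        """Fit distributions and calibration, then score all helix pairs.

        ``distribution_pairs`` is the labelled dataset used for the fg/bg
        gamma fits; each entry of ``calibration_sets`` is a further
        labelled dataset on which a calibration curve is fitted (curves
        are averaged weighted by dataset size).
        """
        dists = fit_strength_distributions(
            self._training_strengths(distribution_pairs), prior=self.prior
        )
        models: list[CalibrationModel] = []
        for dataset in calibration_sets:
            raw_truth = [
                (self._score_block(np.asarray(block), dists), label)
                for block, label in dataset
            ]
            models.append(fit_calibration(raw_truth, bin_size=bin_size,
                                          source_weight=len(dataset)))
        calibration = combine_calibrations(models) if models else None
        predictions = predict_all_pairs(
            self.coupling_matrix, self.annotation, self.template, dists,
            calibration=calibration, aggregation=self.aggregation,
        )
        return HelixInteractionResults(
            model=self, dists=dists, calibrations=models,
            calibration=calibration, predictions=predictions,
        )

    def _score_block(self, block: np.ndarray,
                     dists: StrengthDistributions) -> float:
        """Raw score of a labelled helix-pair block (max over positions)."""
        from scipy import ndimage, special

        llr = dists.llr(block)
        llr_zero = float(dists.llr(np.array([0.0]))[0])
        best = -np.inf
        for orientation in ("parallel", "antiparallel"):
            w = self.template.weights(orientation)
            field_ = ndimage.correlate(llr, w, mode="constant", cval=llr_zero)
            best = max(best, float(field_.max()))
        return float(special.expit(special.logit(self.prior) + best))


@dataclass
class HelixInteractionResults:
    """Fitted detector state plus per-pair predictions."""

    model: HelixInteractionModel
    dists: StrengthDistributions
    calibrations: list[CalibrationModel]
    calibration: CombinedCalibration | None
    predictions: list[HelixPairPrediction]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "helix_a": p.helix_a,
                "helix_b": p.helix_b,
                "orientation": p.orientation,
                "best_offset_i": p.best_offset[0],
                "best_offset_j": p.best_offset[1],
                "raw": p.raw_score,
                "posterior": p.posterior,
            }
            for p in self.predictions
        ])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6f")

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Helix-helix interaction predictions",
            "=" * 51,
            f"helices: {len(self.model.annotation.helices)}   "
            f"pairs: {len(self.predictions)}   "
            f"aggregation: {self.model.aggregation}",
            f"fg ~ Gamma(shape={self.dists.fg_shape:.3g}, "
            f"scale={self.dists.fg_scale:.3g}); "
            f"bg ~ Gamma(shape={self.dists.bg_shape:.3g}, "
            f"scale={self.dists.bg_scale:.3g}); prior={self.dists.prior:.2f}",
        ]
        if self.calibrations:
            for k, c in enumerate(self.calibrations, 1):
                lines.append(
                    f"calibration #{k}: a={c.a:.3f} b={c.b:.3f} "
                    f"c={c.c:.3f} d={c.d:.3f} (weight {c.source_weight:g})"
                )
        else:
            lines.append("calibration: none (posterior = raw score)")
        lines.append("-" * 51)
        lines.append(df.to_string(
            index=False,
            formatters={"raw": "{:.4f}".format, "posterior": "{:.4f}".format},
        ))
        return "\n".join(lines)

    def plot_calibration(self, dataset, ax=None):
        """Diagnostic binned-calibration plot for a labelled dataset."""
        import matplotlib.pyplot as plt

        from .detector import calibration_curve_points

        raw_truth = [
            (self.model._score_block(np.asarray(b), self.dists), y)
            for b, y in dataset
        ]
        xs, ys = calibration_curve_points(raw_truth,
                                          bin_size=self.calibrations[0].bin_size
                                          if self.calibrations else 60)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(xs, ys, "o", label="empirical (binned)")
        grid = np.linspace(0.01, 0.99, 200)
        if self.calibration is not None:
            ax.plot(grid, self.calibration(grid), "-", label="fitted curve")
        ax.plot([0, 1], [0, 1], ":", color="grey", label="identity")
        ax.set_xlabel("raw score")
        ax.set_ylabel("fraction interacting")
        ax.legend()
        return ax
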