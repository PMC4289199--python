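"""Persisted final predictor: linear weights plus encoder parameters.

A trained model is a plain JSON document (weights, bias, C, selected
feature names, encoder parameters) so predictions are reproducible
without retraining or pickling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np

from .encoding import FeatureLayout, PhysicoChemTable, PseDncParams, encode_dataset
from .ranking import LabeledMatrix, fit_linear_svm
from .sequences import DnaSequence


@dataclass
class TrainedModel:
    weights: np.ndarray
    bias: float
    C: float
    feature_names: List[str]
    k_max: int
    omega: int
    weight_w: float

    @classmethod
    def train(
        cls,
        data: LabeledMatrix,
        C: float,
        feature_subset: Sequence[str],
        k_max: int,
        params: PseDncParams,
    ) -> "TrainedModel":
        cols = data.column_indices(feature_subset)
        model = fit_linear_svm(data.X[:, cols], data.y, C)
        return cls(
            weights=model.weights,
            bias=model.bias,
            C=C,
            feature_names=list(feature_subset),
            k_max=k_max,
            omega=params.omega,
            weight_w=params.weight,
        )

    def predict_sequences(
        self, seqs: Sequence[DnaSequence], table: PhysicoChemTable | None = None
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Encode sequences with the stored parameters and score them.

        Returns (labels in {+1, -1}, signed decision values).
        """
        params = PseDncParams(omega=self.omega, weight=self.weight_w)
        X, layout = encode_dataset(seqs, self.k_max, params, table)
        index = {n: i for i, n in enumerate(layout.names)}
        cols = np.array([index[n] for n in self.feature_names])
        decisions = X[:, cols] @ self.weights + self.bias
        return np.where(decisions > 0, 1, -1), decisions

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "weights": self.weights.tolist(),
                    "bias": self.bias,
                    "C": self.C,
                    "feature_names": self.feature_names,
                    "k_max": self.k_max,
                    "omega": self.omega,
                    "weight_w": self.weight_w,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(d["weights"], dtype=float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            feature_names=list(d["feature_names"]),
            k_max=int(d["k_max"]),
            omega=int(d["omega"]),
            weight_w=float(d["weight_w"]),
        )
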