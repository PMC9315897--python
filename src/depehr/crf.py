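"""Linear-chain conditional random field for token sequence tagging.

A compact CRF with binary emission features and a dense label-transition
matrix, trained by maximum likelihood with L2 regularization via L-BFGS
(scipy). Inference is exact: forward-backward for the gradient, Viterbi
for decoding. Sized for the small annotated corpora used in clinical
negation tagging (thousands of sentences, a handful of labels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


@dataclass
class _Sentence:
    feats: list[np.ndarray]  # per-token arrays of feature indices
    labels: np.ndarray  # per-token label indices


class LinearChainCRF:
    """CRF over feature-dict sequences.

    Parameters
    ----------
    labels:
        Fixed, ordered label set.
    l2:
        Gaussian prior precision (L2 penalty weight).
    max_iter:
        L-BFGS iteration cap.
    """

    def __init__(self, labels: list[str], l2: float = 1.0, max_iter: int = 150):
        self.labels = list(labels)
        self.l2 = float(l2)
        self.max_iter = int(max_iter)
        self.feature_index: dict[str, int] = {}
        self.w_emit: np.ndarray | None = None  # (F, L)
        self.w_trans: np.ndarray | None = None  # (L, L)

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: list[list[dict[str, float] | list[str]]],
        y: list[list[str]],
    ) -> "LinearChainCRF":
        if not X:
            raise ValueError("empty training set")
        lab_idx = {l: i for i, l in enumerate(self.labels)}
        self.feature_index = {}
        sents: list[_Sentence] = []
        for feats_seq, labels_seq in zip(X, y):
            tok_feats = []
            for f in feats_seq:
                names = list(f)
                idxs = []
                for name in names:
                    idx = self.feature_index.setdefault(
                        name, len(self.feature_index)
                    )
                    idxs.append(idx)
                tok_feats.append(np.asarray(sorted(set(idxs)), dtype=np.intp))
            sents.append(
                _Sentence(
                    tok_feats,
                    np.asarray([lab_idx[l] for l in labels_seq], dtype=np.intp),
                )
            )
        L = len(self.labels)
        F = len(self.feature_index)
        w0 = np.zeros(F * L + L * L)

        def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
            w_emit = w[: F * L].reshape(F, L)
            w_trans = w[F * L :].reshape(L, L)
            g_emit = np.zeros_like(w_emit)
            g_trans = np.zeros_like(w_trans)
            nll = 0.0
            for s in sents:
                nll += self._sentence_grad(
                    s, w_emit, w_trans, g_emit, g_trans
                )
            nll += 0.5 * self.l2 * float(w @ w)
            grad = np.concatenate([g_emit.ravel(), g_trans.ravel()])
            grad += self.l2 * w
            return nll, grad

        res = minimize(
            objective,
            w0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": 1e-9, "gtol": 1e-6},
        )
        self.w_emit = res.x[: F * L].reshape(F, L)
        self.w_trans = res.x[F * L :].reshape(L, L)
        return self

    def _scores(
        self, feats: list[np.ndarray], w_emit: np.ndarray
    ) -> np.ndarray:
        T = len(feats)
        s = np.zeros((T, w_emit.shape[1]))
        for t, idxs in enumerate(feats):
            if idxs.size:
                s[t] = w_emit[idxs].sum(axis=0)
        return s

    def _sentence_grad(
        self,
        s: _Sentence,
        w_emit: np.ndarray,
        w_trans: np.ndarray,
        g_emit: np.ndarray,
        g_trans: np.ndarray,
    ) -> float:
        T = len(s.feats)
        L = w_emit.shape[1]
        scores = self._scores(s.feats, w_emit)
        # forward / backward in log space
        alpha = np.zeros((T, L))
        alpha[0] = scores[0]
        for t in range(1, T):
            alpha[t] = scores[t] + logsumexp(
                alpha[t - 1][:, None] + w_trans, axis=0
            )
        beta = np.zeros((T, L))
        for t in range(T - 2, -1, -1):
            beta[t] = logsumexp(
                w_trans + (scores[t + 1] + beta[t + 1])[None, :], axis=1
            )
        logZ = logsumexp(alpha[-1])
        # expected counts
        marg = np.exp(alpha + beta - logZ)  # (T, L)
        for t, idxs in enumerate(s.feats):
            if idxs.size:
                np.add.at(g_emit, idxs, marg[t])
        for t in range(1, T):
            pair = np.exp(
                alpha[t - 1][:, None]
                + w_trans
                + (scores[t] + beta[t])[None, :]
                - logZ
            )
            g_trans += pair
        # empirical counts
        path_score = scores[0, s.labels[0]]
        for t, idxs in enumerate(s.feats):
            if idxs.size:
                g_emit[idxs, s.labels[t]] -= 1.0
        for t in range(1, T):
            g_trans[s.labels[t - 1], s.labels[t]] -= 1.0
            path_score += w_trans[s.labels[t - 1], s.labels[t]] + scores[
                t, s.labels[t]
            ]
        return float(logZ - path_score)

    # -- inference ---------------------------------------------------------

    def _encode(self, feats_seq) -> list[np.ndarray]:
        out = []
        for f in feats_seq:
            idxs = [
                self.feature_index[name]
                for name in f
                if name in self.feature_index
            ]
            out.append(np.asarray(sorted(set(idxs)), dtype=np.intp))
        return out

    def predict(self, feats_seq) -> list[str]:
        """Viterbi-decode the most likely label sequence."""
        if self.w_emit is None:
            raise ValueError("model not fitted")
        if not feats_seq:
            return []
        feats = self._encode(feats_seq)
        scores = self._scores(feats, self.w_emit)
        T, L = scores.shape
        delta = np.zeros((T, L))
        back = np.zeros((T, L), dtype=np.intp)
        delta[0] = scores[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + self.w_trans
            back[t] = cand.argmax(axis=0)
            delta[t] = scores[t] + cand.max(axis=0)
        path = [int(delta[-1].argmax())]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [self.labels[i] for i in path]

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        feats = sorted(self.feature_index, key=self.feature_index.get)
        np.savez_compressed(
            path,
            w_emit=self.w_emit,
            w_trans=self.w_trans,
            features=np.asarray(feats, dtype=object),
            labels=np.asarray(self.labels, dtype=object),
            l2=self.l2,
        )

    @classmethod
    def load(cls, path: str) -> "LinearChainCRF":
        with np.load(path, allow_pickle=True) as data:
            model = cls(labels=[str(l) for l in data["labels"]], l2=float(data["l2"]))
            model.w_emit = data["w_emit"]
            model.w_trans = data["w_trans"]
            model.feature_index = {
                str(f): i for i, f in enumerate(data["features"])
            }
        return model


def bio_repair(labels: list[str]) -> list[str]:
    """Deterministic fix for malformed BIO: an I-X not preceded by B-X or
    I-X becomes B-X."""
    fixed = []
    prev = "O"
    for lab in labels:
        if lab.startswith("I-"):
            kind = lab[2:]
            if prev not in (f"B-{kind}", f"I-{kind}"):
                lab = f"B-{kind}"
        fixed.append(lab)
        prev = lab
    return fixed
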