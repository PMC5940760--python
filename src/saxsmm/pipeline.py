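"""End-to-end training and prediction: the consensus mass estimator.

:class:`MMPipeline` owns everything a prediction needs — the mass-bin
scheme, the fitted MoW correction, the V_c power law, the size-and-shape
k-NN index and the four likelihood tables — and exposes

* :meth:`MMPipeline.fit` — train all of it from (profile, true mass) records,
* :meth:`MMPipeline.evidence` — the four per-method estimates for a profile,
* :meth:`MMPipeline.predict` — the Bayesian posterior with MAP mass,
  probability score and 90% credibility interval,
* :meth:`MMPipeline.save` / :meth:`MMPipeline.load` — JSON persistence.

Empirical coefficient models (MoW, V_c, the shape-space index) are fitted on
the ideal (noise-free) training records only; the likelihood tables are then
learned from estimates on *all* training records, ideal and noisy alike, so
that the tables encode each estimator's real error behaviour under noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import bayes
from .estimators import (
    METHODS,
    MMEvidence,
    MowCorrection,
    ShapeSpaceIndex,
    VcPowerLaw,
    estimate_mm_mow,
    estimate_mm_qp,
    estimate_mm_ss,
    estimate_mm_vc,
    fit_mow_correction_from_volumes,
    fit_vc_powerlaw,
)
from .exceptions import NotTrainedError, SaxsmmError
from .guinier import GuinierResult, auto_guinier
from .invariants import InvariantSet, apparent_volume_dimensional, compute_invariants
from .profile_io import ScatteringProfile, load_model, save_model

__all__ = ["TrainingRecord", "MMPipeline", "records_from_corpus"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingRecord:
    """One training profile with its true mass; ``ideal`` marks noise-free data."""

    profile: ScatteringProfile
    mm: float
    ideal: bool = True


def records_from_corpus(entries: Iterable) -> list[TrainingRecord]:
    """Convert synthetic :class:`~saxsmm.synthetic.CorpusEntry` objects to records."""
    return [
        TrainingRecord(profile=e.profile, mm=e.mm, ideal=(e.condition == "ideal"))
        for e in entries
    ]


class MMPipeline:
    """Trainable consensus molecular-mass estimator."""

    def __init__(
        self,
        n_bins: int = 100,
        s_max_mow: float = 0.3,
        s_upper_vc: float = 0.3,
        k_neighbors: int = 5,
    ) -> None:
        self.n_bins = n_bins
        self.s_max_mow = s_max_mow
        self.s_upper_vc = s_upper_vc
        self.k_neighbors = k_neighbors
        self.bins: bayes.BinScheme | None = None
        self.mow: MowCorrection | None = None
        self.vc: VcPowerLaw | None = None
        self.ss: ShapeSpaceIndex | None = None
        self.tables: dict[str, bayes.LikelihoodTable] = {}

    # -- analysis ----------------------------------------------------------

    def analyze(
        self, profile: ScatteringProfile
    ) -> tuple[GuinierResult | None, InvariantSet | None]:
        """Guinier fit plus invariants; either may be None on failure.

        Invariants are computed piecewise so that, e.g., a profile too short
        for the V_c integral still yields a Porod volume — each estimator
        then fails or succeeds on its own inputs.
        """
        try:
            g = auto_guinier(profile)
        except SaxsmmError:
            return None, None
        try:
            inv = compute_invariants(profile, g, s_upper_vc=self.s_upper_vc)
            return g, inv
        except SaxsmmError:
            pass
        # piecewise fallback: keep whatever invariants the data support
        from .invariants import (
            POROD_SRG_CUT,
            apparent_volumes,
            porod_invariant,
            volume_of_correlation,
        )

        qp = vp = vc = np.nan
        v3 = v4 = v5 = np.nan
        truncated = False
        try:
            qp, vp, truncated = porod_invariant(profile, g)
        except SaxsmmError:
            pass
        try:
            vc = volume_of_correlation(profile, g, s_upper=self.s_upper_vc)
        except SaxsmmError:
            pass
        try:
            v3, v4, v5 = apparent_volumes(profile, g)
        except SaxsmmError:
            pass
        if not (np.isfinite(vp) or np.isfinite(vc) or np.isfinite(v3)):
            return g, None
        lc = vp / (2.0 * np.pi * vc) if np.isfinite(vp) and np.isfinite(vc) else np.nan
        inv = InvariantSet(
            qp=qp, vp=vp, vc=vc, lc=lc, vprime_3=v3, vprime_4=v4, vprime_5=v5,
            s_upper_used=min(POROD_SRG_CUT / g.rg, float(profile.s[-1])),
            truncated=truncated,
        )
        return g, inv

    def evidence(
        self,
        profile: ScatteringProfile,
        exclude_self: bool = False,
        _analysis: tuple[GuinierResult | None, InvariantSet | None] | None = None,
    ) -> MMEvidence:
        """The four per-method estimates; failed methods are NaN with a flag."""
        g, inv = _analysis if _analysis is not None else self.analyze(profile)
        ev = MMEvidence()
        if g is None:
            ev.flags = {m: "guinier" for m in METHODS}
            return ev
        if inv is None:
            ev.flags = {m: "invariants" for m in METHODS}
            return ev
        for method, fn in (
            ("mm_qp", lambda: estimate_mm_qp(inv)),
            ("mm_mow", lambda: estimate_mm_mow(profile, g, self.mow)),
            ("mm_vc", lambda: estimate_mm_vc(inv, g, self.vc)),
            ("mm_ss", lambda: estimate_mm_ss(inv, g, self.ss, exclude_self=exclude_self)),
        ):
            try:
                setattr(ev, method, float(fn()))
            except SaxsmmError as exc:
                ev.flags[method] = str(exc)
        return ev

    # -- training ----------------------------------------------------------

    def fit(
        self,
        records: Sequence[TrainingRecord],
        bin_masses: np.ndarray | None = None,
    ) -> "MMPipeline":
        """Train bins, coefficient models and likelihood tables.

        ``bin_masses`` optionally supplies the mass sample the bin scheme is
        built from (e.g. the full corpus rather than the training split);
        by default the unique training masses are used.
        """
        if not records:
            raise SaxsmmError("no training records")
        if bin_masses is None:
            bin_masses = np.array(sorted({r.mm for r in records}))
        self.bins = bayes.build_bins(np.asarray(bin_masses), n_bins=self.n_bins)

        analyses = [self.analyze(r.profile) for r in records]

        # empirical coefficient models from the ideal records
        vprimes, vp_masses, qrs, qr_masses = [], [], [], []
        triplets, rgs, ss_masses = [], [], []
        for rec, (g, inv) in zip(records, analyses):
            if not rec.ideal or g is None or inv is None:
                continue
            try:
                vprimes.append(
                    apparent_volume_dimensional(rec.profile, g, s_max=self.s_max_mow)
                )
                vp_masses.append(rec.mm)
            except SaxsmmError:
                pass
            qrs.append(inv.vc**2 / g.rg)
            qr_masses.append(rec.mm)
            triplets.append([inv.vprime_3, inv.vprime_4, inv.vprime_5])
            rgs.append(g.rg)
            ss_masses.append(rec.mm)
        self.mow = fit_mow_correction_from_volumes(
            np.array(vprimes), np.array(vp_masses), s_max=self.s_max_mow
        )
        self.vc = fit_vc_powerlaw(np.array(qrs), np.array(qr_masses))
        self.ss = ShapeSpaceIndex.build(
            np.array(triplets), np.array(rgs), np.array(ss_masses), k=self.k_neighbors
        )

        # likelihood tables from all records (self-exclusion: the training
        # particle itself sits in the shape-space index)
        pairs: dict[str, list[tuple[float, float]]] = {m: [] for m in METHODS}
        for rec, analysis in zip(records, analyses):
            ev = self.evidence(rec.profile, exclude_self=True, _analysis=analysis)
            for m in METHODS:
                pairs[m].append((getattr(ev, m), rec.mm))
        for m in METHODS:
            if len(pairs[m]) < 1000:
                raise SaxsmmError(
                    f"{len(pairs[m])} training pairs for {m}; at least 1000 required"
                )
            self.tables[m] = bayes.fit_likelihood(m, pairs[m], self.bins)
        return self

    @property
    def trained(self) -> bool:
        return self.bins is not None and len(self.tables) == len(METHODS)

    # -- prediction --------------------------------------------------------

    def predict(
        self,
        profile: ScatteringProfile,
        prior: np.ndarray | None = None,
        exclude_self: bool = False,
    ) -> bayes.PosteriorResult:
        """Bayesian MAP mass with probability score and credibility interval."""
        if not self.trained:
            raise NotTrainedError("pipeline not trained; call fit() or load()")
        ev = self.evidence(profile, exclude_self=exclude_self)
        return bayes.posterior(ev, self.tables, self.bins, prior=prior)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        if not self.trained:
            raise NotTrainedError("nothing to save: pipeline not trained")
        state = {
            "n_bins": self.n_bins,
            "s_max_mow": self.s_max_mow,
            "s_upper_vc": self.s_upper_vc,
            "k_neighbors": self.k_neighbors,
            "bins": {
                "edges": self.bins.edges.tolist(),
                "centers": self.bins.centers.tolist(),
            },
            "mow": {"a": self.mow.a, "b": self.mow.b, "s_max": self.mow.s_max},
            "vc": {"c": self.vc.c, "k": self.vc.k},
            "ss": {
                "points": self.ss.points.tolist(),
                "masses": self.ss.masses.tolist(),
                "mean": self.ss.mean.tolist(),
                "std": self.ss.std.tolist(),
                "k": self.ss.k,
            },
            "tables": {m: t.table.tolist() for m, t in self.tables.items()},
        }
        save_model(state, path)

    @classmethod
    def load(cls, path: str | Path) -> "MMPipeline":
        state = load_model(path)
        pipe = cls(
            n_bins=state["n_bins"],
            s_max_mow=state["s_max_mow"],
            s_upper_vc=state["s_upper_vc"],
            k_neighbors=state["k_neighbors"],
        )
        pipe.bins = bayes.BinScheme(
            edges=np.array(state["bins"]["edges"]),
            centers=np.array(state["bins"]["centers"]),
        )
        pipe.mow = MowCorrection(**state["mow"])
        pipe.vc = VcPowerLaw(**state["vc"])
        ss = state["ss"]
        pipe.ss = ShapeSpaceIndex(
            points=np.array(ss["points"]),
            masses=np.array(ss["masses"]),
            mean=np.array(ss["mean"]),
            std=np.array(ss["std"]),
            k=ss["k"],
        )
        pipe.tables = {
            m: bayes.LikelihoodTable(method=m, table=np.array(t))
            for m, t in state["tables"].items()
        }
        return pipe
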