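"""Per-structure and multi-structure analysis orchestration.

A *scheme name* (``ANM10``, ``ANM13``, ``ANM16``, ``sANM10``, ``sANM13``,
``sdANM``; case-insensitive) resolves to a fully parameterised
:class:`~enmfluct.network.StiffnessScheme` using the bundled tables.  The
single-structure workflow builds the network, runs normal-mode analysis,
rescales the predicted B-factors to the experimental mean and scores the
agreement; the survey workflow repeats this over many structures and
schemes, concatenates per-residue records and stratifies prediction
errors by connectivity, chemistry and secondary structure.  Per-structure
failures (e.g. extra vanishing modes) never abort a survey — they are
tallied with their reason codes, mirroring how entry rejection is part of
the protocol rather than an error.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import data as _data
from .compare import (
    RECORD_COLUMNS,
    bfactor_to_msf,
    classify_chemical,
    classify_secondary,
    pearson_correlation,
    prediction_error,
    stratify,
)
from .network import (
    ConnectivityProfile,
    StiffnessScheme,
    build_network,
    connectivity,
)
from .nma import (
    FluctuationProfile,
    NMAParams,
    assemble_hessian,
    compute_msf,
    diagonalize,
    reject_by_spectrum,
    rescale_to_experiment,
)
from .structures import BeadModel, FilterVerdict, SecondaryStructureRange

__all__ = [
    "SCHEME_NAMES",
    "SurveyConfig",
    "SchemeResult",
    "SingleReport",
    "SurveyResult",
    "resolve_scheme",
    "run_single",
    "run_survey",
    "write_survey_outputs",
]

SCHEME_NAMES = ("anm10", "anm13", "anm16", "sanm10", "sanm13", "sdanm")


def resolve_scheme(name: str) -> StiffnessScheme:
    """Map a scheme name to its parameterisation (case-insensitive).

    Unknown names fail fast, before any computation.
    """
    key = name.lower()
    if key in ("anm10", "anm13", "anm16"):
        return StiffnessScheme.anm(cutoff=float(key[3:]))
    if key in ("sanm10", "sanm13"):
        return StiffnessScheme.sanm(
            cutoff=float(key[4:]), table=_data.sanm_table(),
            backbone_kappa=_data.SANM_BACKBONE_KAPPA,
        )
    if key == "sdanm":
        return StiffnessScheme.sdanm(
            table=_data.sdanm_table(), backbone_kappa=_data.SDANM_BACKBONE_KAPPA,
        )
    raise ValueError(f"unknown scheme name {name!r} (choose from {SCHEME_NAMES})")


@dataclasses.dataclass
class SurveyConfig:
    """Knobs of the analysis workflow.

    ``rescale`` applies the mean-matching of predicted to experimental
    B-factors before per-residue errors are taken (PCC is unaffected
    either way).  ``connectivity_bin_width`` controls the fixed-width
    binning of relative connectivity for stratified summaries.
    """

    schemes: Sequence[str] = ("anm10",)
    rescale: bool = True
    zero_tol: float = 1e-8
    connectivity_bin_width: float = 0.05
    geometric_ss: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("at least one scheme is required")
        # resolve eagerly so unknown names fail before any computation
        self.resolved = {name: resolve_scheme(name) for name in self.schemes}

    @property
    def nma_params(self) -> NMAParams:
        return NMAParams(zero_tol=self.zero_tol)


@dataclasses.dataclass
class SchemeResult:
    """One structure under one scheme."""

    scheme: str
    verdict: FilterVerdict
    profile: FluctuationProfile | None = None
    pcc: float | None = None
    abs_error: np.ndarray | None = None
    connectivity: ConnectivityProfile | None = None


@dataclasses.dataclass
class SingleReport:
    source_id: str
    n_beads: int
    results: dict[str, SchemeResult]
    chem_class: list[str]
    ss_class: list[str]

    def pcc_table(self) -> pd.DataFrame:
        rows = [
            {"source_id": self.source_id, "scheme": name,
             "accepted": int(r.verdict.accepted),
             "pcc": np.nan if r.pcc is None else r.pcc}
            for name, r in self.results.items()
        ]
        return pd.DataFrame(rows, columns=["source_id", "scheme", "accepted", "pcc"])


def run_single(
    beads: BeadModel,
    config: SurveyConfig,
    b_exp: np.ndarray | None = None,
    msf_exp: np.ndarray | None = None,
    ss_annotations: list[SecondaryStructureRange] | None = None,
) -> SingleReport:
    """Analyse one structure under every configured scheme.

    Experimental input is, in order of precedence, an explicit ``msf_exp``
    (e.g. from an NMR ensemble), an explicit ``b_exp``, or the B-factors
    carried by the bead model.  Without any, predictions are produced but
    not scored.  A scheme whose spectrum fails the six-zero-mode criterion
    gets a rejecting verdict and no profile.
    """
    if b_exp is None and msf_exp is None:
        b_exp = beads.b_exp
    if msf_exp is None and b_exp is not None:
        b_exp = np.asarray(b_exp, dtype=float)
        msf_exp = bfactor_to_msf(b_exp)
    elif msf_exp is not None:
        msf_exp = np.asarray(msf_exp, dtype=float)
        b_exp = msf_exp * (8.0 * np.pi**2 / 3.0)

    chem = [classify_chemical(r) for r in beads.residue_names]
    ss = classify_secondary(beads, ss_annotations, geometric_fallback=config.geometric_ss)

    results: dict[str, SchemeResult] = {}
    for name, scheme in config.resolved.items():
        net = build_network(beads, scheme)
        spectrum = diagonalize(assemble_hessian(net), config.nma_params)
        verdict = reject_by_spectrum(spectrum)
        if not verdict.accepted:
            results[name] = SchemeResult(scheme=name, verdict=verdict)
            continue
        profile = compute_msf(spectrum, config.nma_params)
        conn = connectivity(net)
        pcc = None
        err = None
        if msf_exp is not None:
            pcc = pearson_correlation(profile.b_pred, b_exp)
            if config.rescale:
                profile = rescale_to_experiment(profile, b_exp)
            err = prediction_error(profile.msf, msf_exp)
        results[name] = SchemeResult(
            scheme=name, verdict=verdict, profile=profile, pcc=pcc,
            abs_error=err, connectivity=conn,
        )
    return SingleReport(
        source_id=beads.source_id, n_beads=beads.n_beads,
        results=results, chem_class=chem, ss_class=ss,
    )


@dataclasses.dataclass
class SurveyResult:
    records: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    pcc_report: pd.DataFrame
    failures: pd.DataFrame
    n_structures: int

    def mean_pcc(self) -> pd.DataFrame:
        ok = self.pcc_report[self.pcc_report["accepted"] == 1].dropna(subset=["pcc"])
        return (
            ok.groupby("scheme")["pcc"].agg(mean_pcc="mean", n_structures="count").reset_index()
        )


def run_survey(
    structures: Iterable[BeadModel | tuple[BeadModel, list[SecondaryStructureRange] | None]],
    config: SurveyConfig,
) -> SurveyResult:
    """Run the per-structure analysis over a structure set and stratify.

    Each structure must carry experimental B-factors (or be paired with
    secondary-structure annotations via ``(beads, annotations)`` tuples).
    Returns concatenated per-residue records, stratified summaries
    (connectivity bins, chemical class, secondary-structure class,
    scheme), the per-structure PCC report and the failure log.  Output
    rows are sorted canonically, so any processing order yields identical
    tables.
    """
    record_rows: list[dict] = []
    pcc_frames: list[pd.DataFrame] = []
    failure_rows: list[dict] = []
    n_structures = 0

    for item in structures:
        beads, ss_ann = item if isinstance(item, tuple) else (item, None)
        n_structures += 1
        report = run_single(beads, config, ss_annotations=ss_ann)
        pcc_frames.append(report.pcc_table())
        for name, res in report.results.items():
            if not res.verdict.accepted:
                failure_rows.append(
                    {
                        "source_id": report.source_id,
                        "scheme": name,
                        "reasons": ";".join(res.verdict.reasons),
                        "notes": ";".join(res.verdict.notes),
                    }
                )
                continue
            if res.abs_error is None:
                continue
            rel = res.connectivity.relative
            for k in range(report.n_beads):
                record_rows.append(
                    {
                        "source_id": report.source_id,
                        "scheme": name,
                        "bead": k,
                        "chain": beads.chain_ids[k],
                        "seq_number": beads.seq_numbers[k],
                        "residue_name": beads.residue_names[k],
                        "relative_connectivity": float(rel[k]),
                        "abs_error": float(res.abs_error[k]),
                        "chem_class": report.chem_class[k],
                        "ss_class": report.ss_class[k],
                    }
                )

    if not record_rows and not failure_rows:
        raise ValueError("survey received no structures")
    records = pd.DataFrame(record_rows, columns=list(RECORD_COLUMNS))
    records = records.sort_values(["source_id", "scheme", "bead"]).reset_index(drop=True)
    if records.empty:
        raise ValueError("no structure was accepted by the survey")

    summaries = {
        "connectivity": stratify(records, "connectivity", config.connectivity_bin_width),
        "chem_class": stratify(records, "chem_class"),
        "ss_class": stratify(records, "ss_class"),
        "scheme": stratify(records, "scheme"),
    }
    pcc_report = (
        pd.concat(pcc_frames, ignore_index=True)
        .sort_values(["source_id", "scheme"])
        .reset_index(drop=True)
    )
    failures = pd.DataFrame(
        failure_rows, columns=["source_id", "scheme", "reasons", "notes"]
    ).sort_values(["source_id", "scheme"]).reset_index(drop=True)
    return SurveyResult(
        records=records, summaries=summaries, pcc_report=pcc_report,
        failures=failures, n_structures=n_structures,
    )


def write_survey_outputs(result: SurveyResult, config: SurveyConfig, out_dir: str | Path) -> None:
    """Write records, summaries, PCC report, failure log and a manifest."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.8g"
    result.records.to_csv(out / "records.tsv", sep="\t", index=False, float_format=fmt)
    for key, df in result.summaries.items():
        df.to_csv(out / f"summary_{key}.tsv", sep="\t", index=False, float_format=fmt)
    result.pcc_report.to_csv(out / "pcc_report.tsv", sep="\t", index=False, float_format=fmt)
    result.mean_pcc().to_csv(out / "mean_pcc.tsv", sep="\t", index=False, float_format=fmt)
    result.failures.to_csv(out / "failures.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "schemes": list(config.schemes),
        "rescale": config.rescale,
        "zero_tol": config.zero_tol,
        "connectivity_bin_width": config.connectivity_bin_width,
        "geometric_ss": config.geometric_ss,
        "seed": config.seed,
        "n_structures": result.n_structures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
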