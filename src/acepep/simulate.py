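"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a master seed;
per-generator streams are derived by stable labelled sub-seeding, so
adding one generator never perturbs another's output.  Defaults mirror
the scales of a real royal-jelly hydrolysate screen: hydrolysate
activities in the 50-66% range, docking energies between -6.8 and -9.5
kcal/mol, MS abundances around 1e10, triplicate kinetic assays.

Every generator returns the data together with the planted truth, so
downstream stages can be scored without re-deriving it.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import default_rules
from .kinetics import KineticSeries, _four_pl, _michaelis_menten
from .proteome import BioactiveReference, ProteinRecord, default_ace_reference
from .rsm import BBDExperiment, TERM_NAMES
from .scoring import score_candidates

__all__ = [
    "subseed",
    "DEFAULT_TRUE_BETA",
    "BBD_CODED_RUNS",
    "gen_proteome",
    "gen_bbd",
    "gen_kinetics",
    "gen_dose_response",
    "gen_candidates",
    "write_simulation",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def subseed(seed: int, label: str) -> np.random.Generator:
    """Independent stream for one generator, stable in the label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


# ----------------------------------------------------------------- proteome


def gen_proteome(
    seed: int,
    *,
    n_proteins: int = 9,
    length_range: tuple[int, int] = (300, 600),
    motifs: tuple[str, ...] | None = None,
    activity: str = "ACE inhibitor",
    planting_rate: float = 0.02,
    alphabet: str = AMINO_ACIDS,
):
    """Random proteins with bioactive motifs planted at known positions.

    ``planting_rate`` is the expected planted motifs per residue; planted
    copies never overlap each other.  Returns ``(records, reference,
    truth)`` where truth is a DataFrame of (protein_id, motif, position)
    with 1-based start positions covering every *planted* copy (chance
    background occurrences are possible and intended).
    """
    rng = subseed(seed, "proteome")
    if motifs is None:
        ref = default_ace_reference()
        motifs = tuple(sorted(ref.fragments(activity)))
    else:
        motifs = tuple(motifs)
        ref = BioactiveReference([(activity, m) for m in motifs])
    lo, hi = length_range
    max_motif = max(len(m) for m in motifs)
    if max_motif > lo:
        raise ValueError(
            f"longest motif ({max_motif} aa) exceeds the minimum protein length {lo}"
        )
    records, truth_rows = [], []
    for i in range(n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(alphabet), size=n))
        n_plant = rng.binomial(n, planting_rate)
        occupied: list[tuple[int, int]] = []
        for _ in range(n_plant):
            motif = motifs[rng.integers(len(motifs))]
            for _attempt in range(50):
                start = int(rng.integers(0, n - len(motif) + 1))
                span = (start, start + len(motif))
                if all(span[1] <= a or span[0] >= b for a, b in occupied):
                    occupied.append(span)
                    seq[span[0]:span[1]] = list(motif)
                    truth_rows.append(
                        {"protein_id": f"syn{i + 1}", "motif": motif, "position": start + 1}
                    )
                    break
        records.append(
            ProteinRecord(
                id=f"syn{i + 1}",
                sequence="".join(seq),
                description=f"synthetic protein {i + 1}",
            )
        )
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "motif", "position"])
    return records, ref, truth


# ---------------------------------------------------------------------- BBD

#: Standard run order of the three-factor Box-Behnken design.
BBD_CODED_RUNS = np.array(
    [
        (-1, -1, 0), (1, -1, 0), (-1, 1, 0), (1, 1, 0),
        (-1, 0, -1), (1, 0, -1), (-1, 0, 1), (1, 0, 1),
        (0, -1, -1), (0, 1, -1), (0, -1, 1), (0, 1, 1),
        (0, 0, 0), (0, 0, 0), (0, 0, 0), (0, 0, 0), (0, 0, 0),
    ],
    dtype=float,
)

#: Default true coefficients (intercept, A, B, C, AB, AC, BC, A^2, B^2, C^2):
#: effect sizes of a realistic hydrolysis-optimization surface, response in %.
DEFAULT_TRUE_BETA = np.array(
    [65.74, 1.72, 1.68, 1.62, 1.26, 0.23, 0.75, -4.42, -2.82, -7.40]
)


def gen_bbd(seed: int, *, beta=DEFAULT_TRUE_BETA, sigma: float = 0.9):
    """17-run BBD responses from a known quadratic surface + Gaussian noise."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (10,):
        raise ValueError("beta must carry the 10 quadratic-model coefficients")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = subseed(seed, "bbd")
    a, b, c = BBD_CODED_RUNS.T
    X = np.column_stack(
        [np.ones(17), a, b, c, a * b, a * c, b * c, a * a, b * b, c * c]
    )
    y = X @ beta + sigma * rng.standard_normal(17)
    truth = dict(zip(TERM_NAMES, beta))
    return BBDExperiment(coded=BBD_CODED_RUNS.copy(), response=y), truth


# ----------------------------------------------------------------- kinetics


def _apparent_parameters(mode, vmax, km, ki, alpha, inhibitor):
    if mode == "competitive":
        return vmax, km * (1.0 + inhibitor / ki)
    if mode == "non-competitive":
        return vmax / (1.0 + inhibitor / ki), km
    if mode == "mixed":
        denom = 1.0 + inhibitor / (alpha * ki)
        return vmax / denom, km * (1.0 + inhibitor / ki) / denom
    if mode == "none":
        return vmax, km
    raise ValueError(f"unknown inhibition mode {mode!r}")


def gen_kinetics(
    seed: int,
    mode: str = "competitive",
    *,
    vmax: float = 1.0,
    km: float = 1.0,
    ki: float = 10.0,
    alpha: float = 2.0,
    inhibitor_conc: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0),
    n_substrate: int = 6,
    substrate_span: tuple[float, float] = (0.2, 5.0),
    replicates: int = 3,
    noise_cv: float = 0.02,
):
    """Initial-rate series from a chosen inhibition model.

    Substrate concentrations form a geometric series over
    ``substrate_span`` (in multiples of Km), each measured in
    ``replicates`` technical replicates; rates carry multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``.
    """
    if 0.0 not in inhibitor_conc:
        raise ValueError("inhibitor concentrations must include the 0 baseline")
    rng = subseed(seed, f"kinetics:{mode}")
    s_levels = km * np.geomspace(substrate_span[0], substrate_span[1], n_substrate)
    s = np.repeat(s_levels, replicates)
    series = []
    for conc in inhibitor_conc:
        v_app, k_app = _apparent_parameters(mode, vmax, km, ki, alpha, conc)
        clean = _michaelis_menten(s, v_app, k_app)
        noisy = clean * (1.0 + noise_cv * rng.standard_normal(s.size))
        noisy = np.clip(noisy, clean * 1e-3, None)  # rates stay positive
        series.append(KineticSeries(inhibitor_conc=conc, substrate_conc=s, rates=noisy))
    truth = {"mode": mode, "vmax": vmax, "km": km, "ki": ki, "alpha": alpha}
    return series, truth


# ------------------------------------------------------------ dose-response


def gen_dose_response(
    seed: int,
    *,
    ic50: float = 16.9,
    hill: float = 1.0,
    bottom: float = 0.0,
    top: float = 100.0,
    conc: np.ndarray | None = None,
    noise_sd: float = 2.0,
):
    """Inhibition-vs-concentration points from a known 4PL curve.

    The default concentration grid spans two decades around the planted
    IC50 (8 points); noise is additive Gaussian in percentage points,
    emulating triplicate-mean endpoint assays.
    """
    rng = subseed(seed, "dose_response")
    if conc is None:
        conc = ic50 * np.geomspace(0.1, 10.0, 8)
    conc = np.asarray(conc, dtype=float)
    clean = _four_pl(conc, bottom, top, ic50, hill)
    inhibition = clean + noise_sd * rng.standard_normal(conc.size)
    truth = {"ic50": ic50, "hill": hill, "bottom": bottom, "top": top}
    return conc, inhibition, truth


# -------------------------------------------------------------- candidates


def gen_candidates(
    seed: int,
    *,
    n: int = 57,
    log10_abundance: tuple[float, float] = (10.0, 0.35),
    confidence_range: tuple[float, float] = (395.0, 425.0),
    energy_range: tuple[float, float] = (-9.5, -6.8),
    length_range: tuple[int, int] = (5, 8),
):
    """Candidate-peptide table with an analytically known truth ranking.

    Abundances are log-normal (``log10_abundance`` = mean, sd of log10),
    confidences and binding energies uniform over their ranges; the truth
    score card is computed with the package's own scoring defaults.
    """
    rng = subseed(seed, "candidates")
    sequences: list[str] = []
    seen = set()
    while len(sequences) < n:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        if seq not in seen:
            seen.add(seq)
            sequences.append(seq)
    table = pd.DataFrame(
        {
            "sequence": sequences,
            "abundance": 10.0 ** rng.normal(*log10_abundance, size=n),
            "confidence": rng.uniform(*confidence_range, size=n),
            "binding_energy": rng.uniform(*energy_range, size=n),
        }
    )
    truth = score_candidates(table)
    return table, truth


# ------------------------------------------------------------------ export


def write_simulation(outdir, seed: int, **overrides) -> dict:
    """Generate one complete input set and write it as plain-text files.

    Produces FASTA + reference TSV, a natural-units design CSV, candidate
    and kinetics and dose-response CSVs, and a ``truth.json`` holding all
    planted parameters.  Returns the truth dictionary.
    """
    from .rsm import DEFAULT_CODING  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, ref, motif_truth = gen_proteome(seed, **overrides.get("proteome", {}))
    with open(outdir / "proteome.fasta", "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.description}\n")
            for k in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[k:k + 60] + "\n")
    with open(outdir / "reference.tsv", "w") as fh:
        fh.write("activity\tsequence\n")
        for activity, frag in sorted(ref.entries):
            fh.write(f"{activity}\t{frag}\n")

    design, beta_truth = gen_bbd(seed, **overrides.get("bbd", {}))
    nat = {
        name: [DEFAULT_CODING.decode(name, v) for v in design.coded[:, i]]
        for i, name in enumerate(DEFAULT_CODING.names)
    }
    pd.DataFrame({**nat, "activity": design.response}).to_csv(
        outdir / "design.csv", index=False
    )

    candidates, truth_card = gen_candidates(seed, **overrides.get("candidates", {}))
    candidates.to_csv(outdir / "candidates.csv", index=False)

    series, kin_truth = gen_kinetics(seed, **overrides.get("kinetics", {}))
    kin_rows = [
        {"inhibitor_conc": s.inhibitor_conc, "substrate_conc": sc, "rate": r}
        for s in series
        for sc, r in zip(s.substrate_conc, s.rates)
    ]
    pd.DataFrame(kin_rows).to_csv(outdir / "kinetics.csv", index=False)

    conc, inhibition, dr_truth = gen_dose_response(seed, **overrides.get("dose_response", {}))
    pd.DataFrame({"conc": conc, "inhibition": inhibition}).to_csv(
        outdir / "dose_response.csv", index=False
    )

    truth = {
        "seed": int(seed),
        "proteome": {
            "planted_motifs": motif_truth.to_dict(orient="records"),
            "enzymes": [r.name for r in default_rules()],
        },
        "bbd_beta": {k: float(v) for k, v in beta_truth.items()},
        "candidate_ranking": truth_card["sequence"].tolist(),
        "kinetics": kin_truth,
        "dose_response": dr_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
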