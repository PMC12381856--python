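"""Synthetic inputs with known ground truth for every pipeline stage.

Generators cover: multi-scan-rate melt curves and isothermal unfolding
traces from known kinetic parameters; hidden-Markov 1-D RMSD series
with a known macrostate structure; coarse one-bead-per-residue
conformer ensembles with planted burial-to-exposure changes; and
aggregation-score profiles with planted APRs plus matching random
sequences and mutation strings.

Every generator draws from a single ``numpy.random.default_rng`` seeded
stream, so regeneration with the same parameters and seed is
bit-identical.  Default kinetic truth places the DSC peak in the
325-345 K range with a 1-3 K shift across scan rates of 0.5-2 K/min,
the regime typical of kinetically controlled protein unfolding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import (
    ExperimentCurve,
    KineticParams,
    dsc_signal,
    propagate_isothermal,
    propagate_scan,
    spectro_signal,
)
from .msm import FeatureSeries
from .sasa import StructureFrame, sphere_points
from .tables import AMINO_ACIDS

DEFAULT_TRUTH = KineticParams(
    Ea1=300.0, Tstar1=333.0, Ea2=250.0, Tstar2=341.0,
    dHcal1=450.0, dHcal2=0.0,
)

DEFAULT_SCAN_RATES = (0.5, 1.0, 2.0)  # K/min
DEFAULT_ISO_TEMPS = (323.15, 333.15, 343.15, 353.15)  # K, 50-80 degC

DEFAULT_BASELINES = {
    # per-state (a, b): intercept at Tref and slope per K
    "DSF_BCM": {"N": (330.0, 0.010), "I": (338.0, 0.020), "D": (347.0, 0.010)},
    "CD": {"N": (-20.0, 0.020), "I": (-12.0, 0.030), "D": (-4.0, 0.010)},
    "ISOTHERMAL": {"N": (-20.0, 0.0), "I": (-12.0, 0.0), "D": (-4.0, 0.0)},
}


@dataclass
class SyntheticBundle:
    """Generated datasets plus the ground truth that produced them."""

    seed: int
    truth_params: KineticParams | None = None
    curves: list = field(default_factory=list)
    isothermal: list = field(default_factory=list)
    feature_series: FeatureSeries | None = None
    true_macro_labels: list | None = None
    macro_transition: np.ndarray | None = None
    ensembles: dict | None = None
    ensemble_sequence: str | None = None
    planted_exposed: set | None = None
    max_sasa_table: dict | None = None
    sequence: str | None = None
    profile: np.ndarray | None = None
    planted_aprs: list | None = None
    mutation_string: str | None = None
    noise_settings: dict = field(default_factory=dict)


def _add_noise(rng, y, noise_sd):
    if noise_sd == 0:
        return y
    amp = np.ptp(y)
    return y + rng.normal(0.0, noise_sd * (amp if amp > 0 else 1.0), size=y.shape)


def gen_thermal_datasets(
    truth: KineticParams = DEFAULT_TRUTH,
    scan_rates=DEFAULT_SCAN_RATES,
    techniques=("DSC", "DSF_BCM"),
    noise_sd: float = 0.02,
    seed: int = 0,
    T0: float = 293.15,
    T1: float = 363.15,
    n_points: int = 150,
    baselines: dict | None = None,
    Tref: float = 298.15,
) -> list[ExperimentCurve]:
    """Forward-model melt curves plus i.i.d. Gaussian noise.

    ``noise_sd`` is a fraction of each curve's signal amplitude.  DSC is
    generated at every requested scan rate, spectroscopic techniques
    likewise with the default per-state linear baselines.
    """
    rng = np.random.default_rng(seed)
    base = DEFAULT_BASELINES if baselines is None else baselines
    out = []
    for v in scan_rates:
        frac = propagate_scan(truth, T0, T1, v, n_grid=n_points)
        for tech in techniques:
            if tech == "DSC":
                y = dsc_signal(truth, frac, v)
            else:
                y = spectro_signal(frac, base[tech], Tref=Tref)
            out.append(ExperimentCurve(
                technique=tech, x=frac.grid.copy(), y=_add_noise(rng, y, noise_sd),
                scan_rate=v, name=f"{tech}@{v}K_min",
                baseline_params=None if tech == "DSC" else dict(base[tech]),
            ))
    return out


def gen_isothermal_traces(
    truth: KineticParams = DEFAULT_TRUTH,
    temps=DEFAULT_ISO_TEMPS,
    duration: float = 120.0,
    n_points: int = 80,
    noise_sd: float = 0.02,
    seed: int = 0,
    baselines: dict | None = None,
) -> list[ExperimentCurve]:
    """Isothermal unfolding traces (constant per-state signals plus noise)."""
    for T in temps:
        if not (273.0 <= T <= 380.0):
            raise ValueError(f"hold temperature {T} K outside 273-380 K")
    rng = np.random.default_rng(seed)
    base = (DEFAULT_BASELINES["ISOTHERMAL"] if baselines is None else baselines)
    times = np.linspace(0.0, duration, n_points)
    out = []
    for T in temps:
        frac = propagate_isothermal(truth, T, times)
        y = spectro_signal(frac, base)
        out.append(ExperimentCurve(
            technique="ISOTHERMAL", x=times.copy(),
            y=_add_noise(rng, y, noise_sd),
            hold_temperature=float(T), name=f"iso@{T:.2f}K",
            baseline_params=dict(base),
        ))
    return out


def gen_sls_curve(
    truth: KineticParams = DEFAULT_TRUTH,
    v: float = 1.0,
    follows: str = "I",
    amplitude: float = 4000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    T0: float = 293.15,
    T1: float = 363.15,
    n_points: int = 150,
) -> ExperimentCurve:
    """Static-light-scattering trace tracking a chosen species' fraction."""
    rng = np.random.default_rng(seed)
    frac = propagate_scan(truth, T0, T1, v, n_grid=n_points)
    series = {"I": frac.xI, "D": frac.xD, "I+D": frac.xI + frac.xD}[follows]
    y = amplitude * series
    return ExperimentCurve(technique="SLS", x=frac.grid.copy(),
                           y=_add_noise(rng, y, noise_sd), scan_rate=v,
                           name=f"SLS@{v}K_min")


DEFAULT_MACRO_T = np.array([
    [0.98, 0.02, 0.00],
    [0.01, 0.98, 0.01],
    [0.00, 0.02, 0.98],
])
DEFAULT_EMISSIONS = ((2.0, 1.0), (8.0, 1.0), (14.0, 1.0))


def gen_markov_feature_series(
    macro_T: np.ndarray = DEFAULT_MACRO_T,
    emissions=DEFAULT_EMISSIONS,
    n_traj: int = 10,
    n_frames: int = 2000,
    seed: int = 0,
    frame_interval_ns: float = 0.1,
):
    """Hidden-Markov RMSD series with known macrostate truth.

    Macrostate paths are sampled from ``macro_T`` (initial states from
    its stationary distribution); emissions are Gaussian per state,
    clipped at zero.  Returns ``(FeatureSeries, true_labels)``.
    """
    macro_T = np.asarray(macro_T, dtype=float)
    if macro_T.ndim != 2 or macro_T.shape[0] != macro_T.shape[1]:
        raise ValueError("macro_T must be square")
    if not np.allclose(macro_T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("macro_T rows must sum to 1")
    means = np.array([e[0] for e in emissions])
    sds = np.array([e[1] for e in emissions])
    if len(set(means.tolist())) != means.size:
        raise ValueError("emission means must be distinct")
    n_states = macro_T.shape[0]
    from .msm import stationary_distribution

    pi = stationary_distribution(macro_T)
    rng = np.random.default_rng(seed)
    trajs, labels = [], []
    for _ in range(n_traj):
        states = np.empty(n_frames, dtype=int)
        states[0] = rng.choice(n_states, p=pi)
        for t in range(1, n_frames):
            states[t] = rng.choice(n_states, p=macro_T[states[t - 1]])
        values = np.clip(rng.normal(means[states], sds[states]), 0.0, None)
        trajs.append(values)
        labels.append(states)
    return FeatureSeries(trajs, frame_interval_ns), labels


def gen_toy_ensemble(
    n_residues: int = 56,
    patch=None,
    jitter_sd: float = 0.1,
    n_frames: int = 10,
    seed: int = 0,
    bead_radius: float = 1.7,
    probe: float = 1.4,
    shell_radius: float = 4.0,
    open_radius: float = 14.0,
):
    """Coarse one-bead-per-residue two-state ensembles with a planted
    burial-to-exposure patch.

    The "native" state sequesters the patch residues inside a closed
    shell formed by the remaining beads; the "intermediate" state
    translates the patch outward along +x where each bead is fully
    solvent accessible.  Per-frame Gaussian jitter emulates thermal
    motion.  Returns a dict with the two ensembles, the random sequence,
    the planted newly-exposed residue set (1-based) and a matching
    SASA_max table (isolated-bead area) for rASA normalisation.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    rng = np.random.default_rng(seed)
    if patch is None:
        mid = n_residues // 2
        patch = list(range(mid - 2, mid + 4))  # 6 residues, 1-based below
    patch = sorted(int(p) for p in patch)
    n_patch = len(patch)
    if n_patch >= n_residues - 8:
        raise ValueError("patch too large for a closing shell")
    shell_ids = [i for i in range(1, n_residues + 1) if i not in patch]

    shell_xyz = shell_radius * sphere_points(len(shell_ids))
    inner_xyz = 1.0 * sphere_points(max(n_patch, 2))[:n_patch]
    open_xyz = np.column_stack([
        open_radius + 4.5 * np.arange(n_patch),
        np.zeros(n_patch), np.zeros(n_patch),
    ])

    def build(patch_xyz):
        coords = np.empty((n_residues, 3))
        for j, rid in enumerate(shell_ids):
            coords[rid - 1] = shell_xyz[j]
        for j, rid in enumerate(patch):
            coords[rid - 1] = patch_xyz[j]
        return coords

    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n_residues))
    radii = np.full(n_residues, bead_radius)
    res_idx = np.arange(1, n_residues + 1)
    rtype = np.array(list(sequence))

    ensembles = {}
    for state, xyz in (("native", build(inner_xyz)), ("intermediate", build(open_xyz))):
        frames = []
        for _ in range(n_frames):
            jitter = rng.normal(0.0, jitter_sd, size=xyz.shape) if jitter_sd > 0 else 0.0
            frames.append(StructureFrame(
                coords=xyz + jitter, radii=radii.copy(),
                residue_index=res_idx.copy(), residue_type=rtype.copy(),
            ))
        ensembles[state] = frames

    isolated_area = 4.0 * np.pi * (bead_radius + probe) ** 2
    max_table = {aa: isolated_area for aa in AMINO_ACIDS}
    return {
        "ensembles": ensembles,
        "sequence": sequence,
        "planted_exposed": set(patch),
        "max_sasa_table": max_table,
        "probe": probe,
    }


def gen_profiles_and_sequences(
    n_residues: int = 296,
    planted_aprs=((160, 185), (260, 280)),
    apr_score: float = 0.6,
    background: float = 0.1,
    seed: int = 0,
    n_mutations: int = 0,
):
    """Aggregation-score profile with planted APRs + random sequence.

    Background residues score around ``background`` (jittered within
    [0.02, 0.22]); planted ranges score around ``apr_score``.
    Overlapping planted ranges are merged with a warning.  Optionally
    emits a mutation string consistent with the sequence.

    Returns ``(profile, sequence, planted_ranges, mutation_string)``.
    """
    rng = np.random.default_rng(seed)
    ranges = sorted((int(a), int(b)) for a, b in planted_aprs)
    for a, b in ranges:
        if not (1 <= a <= b <= n_residues):
            raise ValueError(f"planted range {(a, b)} outside the sequence")
    merged = []
    for a, b in ranges:
        if merged and a <= merged[-1][1] + 1:
            warnings.warn("overlapping planted APR ranges merged", stacklevel=2)
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    profile = np.clip(
        background + rng.normal(0.0, 0.03, n_residues), 0.02, 0.22)
    for a, b in merged:
        profile[a - 1:b] = np.clip(
            apr_score + rng.normal(0.0, 0.05, b - a + 1), 0.30, 1.0)
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n_residues))
    mut_string = None
    if n_mutations:
        positions = np.sort(rng.choice(n_residues, size=n_mutations, replace=False)) + 1
        toks = []
        for p in positions:
            wt = sequence[p - 1]
            mut = rng.choice([aa for aa in AMINO_ACIDS if aa != wt])
            toks.append(f"{wt}{p}{mut}")
        mut_string = " + ".join(toks)
    return profile, sequence, merged, mut_string


def gen_bundle(seed: int = 0, noise_sd: float = 0.02,
               truth: KineticParams = DEFAULT_TRUTH) -> SyntheticBundle:
    """Convenience: one bundle exercising every pipeline stage."""
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=5)]
    curves = gen_thermal_datasets(truth, noise_sd=noise_sd, seed=sub[0])
    iso = gen_isothermal_traces(truth, noise_sd=noise_sd, seed=sub[1])
    series, labels = gen_markov_feature_series(seed=sub[2])
    toy = gen_toy_ensemble(seed=sub[3])
    profile, sequence, ranges, muts = gen_profiles_and_sequences(
        seed=sub[4], n_mutations=8)
    return SyntheticBundle(
        seed=seed, truth_params=truth, curves=curves, isothermal=iso,
        feature_series=series, true_macro_labels=labels,
        macro_transition=DEFAULT_MACRO_T.copy(),
        ensembles=toy["ensembles"], ensemble_sequence=toy["sequence"],
        planted_exposed=toy["planted_exposed"],
        max_sasa_table=toy["max_sasa_table"], sequence=sequence,
        profile=profile, planted_aprs=ranges, mutation_string=muts,
        noise_settings={"noise_sd": noise_sd},
    )
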