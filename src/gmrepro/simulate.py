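"""Synthetic multi-operator landmark datasets with known ground truth.

The generator emulates the structure of a two-river, four-operator
digitisation study of salmonid body shape: a 22-landmark template
(15 fixed + 7 sliding semi-landmarks; landmarks 21 and 22 sit on the
lateral line and are used only to correct body arching), a small
between-river mean-shape difference, low-rank individual biological
variation, an allometric size effect, per-operator systematic bias
concentrated on the head landmarks, small intra-operator trial noise,
per-specimen quadratic body arching, and a random similarity embedding
standing in for the photograph's frame and the fish's size.

Default magnitudes are expressed in shape units (template centroid
size 1) and were chosen so that the standard downstream analyses land
in the regimes typical of field photographs of live salmonids
(between-river r² of a few percent, allometry r² ≈ 0.02-0.03,
repeatability ≈ 0.95, operator mean-shape distances ≈ 0.01); the
derivations are in the methods note.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .base import LandmarkConfiguration, LandmarkScheme, ShapeDataset, shuffle_blind
from .gpa import centroid_size
from . import tps

HEAD_LANDMARKS = tuple(range(1, 13))   # the less discrete head points, 1-based

_TEMPLATE_RAW = np.array(
    [
        (0.000, 0.000),    # 1  tip of snout
        (0.065, 0.055),    # 2  midpoint of dorsal head profile between 1 and 3
        (0.130, 0.090),    # 3  directly above middle of eye
        (0.130, 0.000),    # 4  lateral line below 3
        (0.130, 0.048),    # 5  top of eye
        (0.130, 0.002),    # 6  bottom of eye
        (0.155, 0.025),    # 7  posterior of eye
        (0.105, 0.025),    # 8  anterior of eye
        (0.140, -0.035),   # 9  end of maxillary bone
        (0.270, -0.020),   # 10 posterior tip of operculum
        (0.300, 0.100),    # 11 dorsal posterior of cranium
        (0.300, 0.000),    # 12 lateral line below 11
        (0.450, 0.130),    # 13 anterior insertion of dorsal fin
        (0.780, 0.090),    # 14 anterior insertion of adipose fin
        (0.930, 0.060),    # 15 dorsal insertion of caudal fin
        (0.930, 0.000),    # 16 lateral line below 15
        (1.000, 0.000),    # 17 posterior midpoint of hypural plate
        (0.700, -0.090),   # 18 anterior insertion of anal fin
        (0.520, -0.100),   # 19 anterior insertion of ventral fin
        (0.280, -0.075),   # 20 anterior insertion of pectoral fin
        (0.450, 0.000),    # 21 lateral line below 13 (arching reference)
        (0.700, 0.000),    # 22 lateral line below 18 (arching reference)
    ]
)


def make_template() -> np.ndarray:
    """The 22-landmark salmonid template, centred with unit centroid size.

    Landmarks 1, 21, 22 and 17 lie exactly on the lateral-line axis (the
    unbending references are collinear by construction).
    """
    t = _TEMPLATE_RAW - _TEMPLATE_RAW.mean(axis=0)
    return t / centroid_size(t)


def salmon_scheme() -> LandmarkScheme:
    """The 22-landmark scheme: 15 fixed, 7 sliding semi-landmarks,
    unbending through 1-21-22-17, landmarks 21-22 excluded from
    statistics."""
    semi = {2, 4, 5, 6, 11, 12, 16}
    return LandmarkScheme(
        n_landmarks=22,
        fixed=frozenset(set(range(1, 23)) - semi),
        semi=frozenset(semi),
        slide_neighbours={
            2: (1, 3),     # dorsal head profile
            4: (1, 12),    # lateral line
            5: (8, 7),     # eye outline
            6: (8, 7),
            11: (3, 13),   # dorsal profile
            12: (4, 16),   # lateral line
            16: (12, 17),  # lateral line
        },
        unbend=(1, 21, 22, 17),
        excluded=frozenset({21, 22}),
    )


def _anatomical_direction(template: np.ndarray) -> np.ndarray:
    """Deterministic 'deep body, pointed snout, large eye' contrast."""
    d = np.zeros_like(template)
    d[12] = (0.0, 1.0)     # 13 dorsal fin up
    d[13] = (0.0, 0.7)     # 14 adipose up
    d[17] = (0.0, -1.0)    # 18 anal fin down
    d[18] = (0.0, -0.8)    # 19 ventral fin down
    d[0] = (-0.8, 0.0)     # 1 snout forward
    d[8] = (0.5, 0.0)      # 9 longer mouth
    d[4] = (0.0, 0.35)     # 5 eye taller
    d[5] = (0.0, -0.35)    # 6
    d[6] = (0.3, 0.0)      # 7 eye wider
    d[7] = (-0.3, 0.0)     # 8
    d[14] = (0.0, 0.4)     # 15 deeper caudal peduncle
    d -= d.mean(axis=0)
    return d / np.linalg.norm(d)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters of the synthetic digitisation experiment.

    Magnitudes are in shape units (template centroid size = 1) unless
    noted. ``operator_bias_magnitude`` is the norm of each operator's
    systematic displacement field (supported on ``bias_landmarks``
    only); ``trial_noise_sd`` is the isotropic per-landmark digitising
    SD, with semi-landmarks receiving ``semi_tangent_factor`` times that
    SD along their tangent. Fish size enters as a uniform log centroid
    size (mm) driving both the embedding scale and the allometric shape
    effect of ``allometry_magnitude`` per unit log size.
    """

    n_per_group: Mapping = dataclasses.field(
        default_factory=lambda: {"Spey": 144, "Oykel": 147}
    )
    n_operators: int = 4
    group_effect_magnitude: float = 0.0052
    group_effect_mode_weights: tuple = (0.5, 0.4)
    operator_bias_magnitude: float = 0.010
    bias_landmarks: tuple = HEAD_LANDMARKS
    trial_noise_sd: float = 7e-4
    semi_tangent_factor: float = 2.0
    individual_mode_sd: tuple = (0.010, 0.008, 0.006, 0.0045, 0.0035)
    allometry_magnitude: float = 0.022
    log_size_range: tuple = (np.log(110.0), np.log(160.0))
    bend_curvature_range: tuple = (-0.15, 0.15)
    n_replicate_per_group: int = 10
    n_trials: int = 3
    digitising_scale: float = 0.25    # mm per pixel in written TPS fixtures
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.n_per_group.values()):
            raise ValueError("group counts must be positive")
        if self.n_operators < 1:
            raise ValueError("need at least one operator")
        if self.trial_noise_sd < 0 or self.operator_bias_magnitude < 0:
            raise ValueError("noise and bias magnitudes must be non-negative")
        if self.n_replicate_per_group > min(self.n_per_group.values()):
            raise ValueError("replicate subset larger than a group")

    @property
    def operators(self) -> list:
        return [f"Op.{i + 1}" for i in range(self.n_operators)]


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth components behind a simulated dataset.

    ``shape_space_observations`` are the observed digitisations in the
    template frame *before* arching and the similarity embedding (rows
    aligned with the dataset): the oracle for recovery tests.
    """

    template: np.ndarray
    scheme: LandmarkScheme
    group_effect: np.ndarray          # (k, 2) second group minus first
    operator_bias: np.ndarray         # (n_ops, k, 2)
    operators: list
    allometry_vector: np.ndarray      # (k, 2) per unit log size
    individual_modes: np.ndarray      # (n_modes, k, 2)
    specimens: pd.DataFrame           # specimen_id, group, log_size, bend, rotation, tx, ty
    true_shapes: np.ndarray           # (n_specimens, k, 2)
    shape_space_observations: np.ndarray  # (N_rows, k, 2)
    trial_noise_sd: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "trial_noise_sd": self.trial_noise_sd,
            "operators": self.operators,
            "scheme": self.scheme.to_dict(),
            "template": self.template.tolist(),
            "group_effect": self.group_effect.tolist(),
            "operator_bias": self.operator_bias.tolist(),
            "allometry_vector": self.allometry_vector.tolist(),
            "individual_modes": self.individual_modes.tolist(),
            "specimens": self.specimens.to_dict(orient="list"),
            "true_shapes": np.round(self.true_shapes, 9).tolist(),
            "shape_space_observations": np.round(self.shape_space_observations, 9).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            template=np.array(d["template"]),
            scheme=LandmarkScheme.from_dict(d["scheme"]),
            group_effect=np.array(d["group_effect"]),
            operator_bias=np.array(d["operator_bias"]),
            operators=list(d["operators"]),
            allometry_vector=np.array(d["allometry_vector"]),
            individual_modes=np.array(d["individual_modes"]),
            specimens=pd.DataFrame(d["specimens"]),
            true_shapes=np.array(d["true_shapes"]),
            shape_space_observations=np.array(d["shape_space_observations"]),
            trial_noise_sd=float(d["trial_noise_sd"]),
            seed=int(d["seed"]),
        )


def _orthonormal_modes(rng: np.random.Generator, k: int, n_modes: int,
                       straight0: np.ndarray) -> np.ndarray:
    """Random centred, mutually orthonormal shape-space directions.

    The y components at the ``straight0`` landmarks (the arching
    references on the lateral line) are zeroed: biological variation
    moves points along that naturally straight axis but does not bend
    it, which is the anatomical premise of unbending.
    """
    raw = rng.normal(size=(n_modes, k, 2))
    raw[:, straight0, 1] = 0.0      # equal (after centring) y on the axis
    raw -= raw.mean(axis=1, keepdims=True)
    flat = raw.reshape(n_modes, -1)
    q, _ = np.linalg.qr(flat.T)
    return q.T[:n_modes].reshape(n_modes, k, 2)


def simulate_dataset(spec: SyntheticSpec):
    """Simulate the full multi-operator digitisation experiment.

    Returns the observed :class:`ShapeDataset` (coordinates in mm, as a
    digitiser with a calibrated scale would record them) and the
    :class:`SyntheticTruth` behind it. Row order: operator-major, then
    specimen, then trial.
    """
    rng = np.random.default_rng(spec.seed)
    template = make_template()
    scheme = salmon_scheme()
    k = scheme.n_landmarks

    straight0 = scheme.unbend0
    modes = _orthonormal_modes(rng, k, len(spec.individual_mode_sd), straight0)
    anat = _anatomical_direction(template)
    # group difference partly inside the individual-variation subspace
    # (real between-population contrasts are not orthogonal to within-
    # population variation), remainder along the anatomical contrast
    w = np.asarray(spec.group_effect_mode_weights, float)
    w_res = float(np.sqrt(max(1.0 - (w ** 2).sum(), 0.0)))
    flat_modes = modes.reshape(len(modes), -1)
    anat_flat = anat.ravel()
    anat_orth = anat_flat - flat_modes.T @ (flat_modes @ anat_flat)
    anat_orth /= np.linalg.norm(anat_orth)
    gdir = w_res * anat_orth
    for wi, mode in zip(w, flat_modes):
        gdir = gdir + wi * mode
    gdir /= np.linalg.norm(gdir)
    group_effect = spec.group_effect_magnitude * gdir.reshape(k, 2)

    adir = rng.normal(size=(k, 2))
    adir[straight0, 1] = 0.0        # allometric growth keeps the axis straight
    adir -= adir.mean(axis=0)
    allometry = spec.allometry_magnitude * adir / np.linalg.norm(adir)

    bias = np.zeros((spec.n_operators, k, 2))
    mask0 = np.array([i - 1 for i in spec.bias_landmarks], dtype=int)
    for o in range(spec.n_operators):
        raw = np.zeros((k, 2))
        raw[mask0] = rng.normal(size=(mask0.size, 2))
        norm = np.linalg.norm(raw)
        if norm > 0 and spec.operator_bias_magnitude > 0:
            raw *= spec.operator_bias_magnitude / norm
        else:
            raw[:] = 0.0
        bias[o] = raw

    groups = list(spec.n_per_group)
    specimen_rows = []
    true_shapes = []
    mean_log_size = float(np.mean(spec.log_size_range))
    for gi, g in enumerate(groups):
        for j in range(spec.n_per_group[g]):
            sid = f"{g}_{j + 1:03d}"
            log_size = float(rng.uniform(*spec.log_size_range))
            z = rng.normal(size=len(spec.individual_mode_sd))
            deviation = np.tensordot(z * np.asarray(spec.individual_mode_sd), modes, axes=1)
            # symmetric +/- half effect keeps the grand mean at the template
            sign = +0.5 if gi == 1 else -0.5 if gi == 0 else 0.0
            shape = (
                template
                + sign * group_effect
                + deviation
                + (log_size - mean_log_size) * allometry
            )
            bend = float(rng.uniform(*spec.bend_curvature_range))
            rot = float(rng.uniform(-np.pi, np.pi))
            tx, ty = rng.uniform(0.0, 300.0, size=2)
            specimen_rows.append(
                dict(specimen_id=sid, group=g, log_size=log_size, bend=bend,
                     rotation=rot, tx=float(tx), ty=float(ty),
                     replicate=j < spec.n_replicate_per_group)
            )
            true_shapes.append(shape)
    specimens = pd.DataFrame(specimen_rows)
    true_shapes = np.stack(true_shapes)

    # semi-landmark tangents (template chord) for the extra tangential noise
    semi0, prev0, next0 = scheme.semi0, scheme.prev0, scheme.next0
    tang = template[next0] - template[prev0]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    extra_sd = spec.trial_noise_sd * np.sqrt(max(spec.semi_tangent_factor ** 2 - 1.0, 0.0))

    xc = 0.5 * (template[scheme.unbend0[0], 0] + template[scheme.unbend0[-1], 0])
    coords = []
    obs_shape_space = []
    fac_rows = []
    for o, op in enumerate(spec.operators):
        for s in range(len(specimens)):
            row = specimens.iloc[s]
            n_tr = spec.n_trials if row["replicate"] else 1
            for trial in range(1, n_tr + 1):
                noise = rng.normal(0.0, spec.trial_noise_sd, size=(k, 2))
                if extra_sd > 0 and semi0.size:
                    noise[semi0] += rng.normal(0.0, extra_sd, size=semi0.size)[:, None] * tang
                obs = true_shapes[s] + bias[o] + noise
                obs_shape_space.append(obs)
                arched = obs.copy()
                arched[:, 1] += row["bend"] * (obs[:, 0] - xc) ** 2
                c, sn = np.cos(row["rotation"]), np.sin(row["rotation"])
                R = np.array([[c, -sn], [sn, c]])
                size_mm = float(np.exp(row["log_size"]))
                coords.append(size_mm * (arched @ R.T) + np.array([row["tx"], row["ty"]]))
                fac_rows.append(
                    dict(specimen_id=row["specimen_id"], group=row["group"],
                         operator=op, trial=trial)
                )
    dataset = ShapeDataset(np.stack(coords), pd.DataFrame(fac_rows), scheme)
    truth = SyntheticTruth(
        template=template,
        scheme=scheme,
        group_effect=group_effect,
        operator_bias=bias,
        operators=spec.operators,
        allometry_vector=allometry,
        individual_modes=modes,
        specimens=specimens,
        true_shapes=true_shapes,
        shape_space_observations=np.stack(obs_shape_space),
        trial_noise_sd=spec.trial_noise_sd,
        seed=spec.seed,
    )
    return dataset, truth


# ----------------------------------------------------------------------
# fixtures on disk

def write_fixtures(spec: SyntheticSpec, directory) -> dict:
    """Write the simulated experiment as TPS fixtures.

    Per operator: a main TPS file (every specimen once, in an
    operator-specific blinded shuffle) and a replicates TPS file (the
    replicate subset, trial-major, so re-reading infers trials from
    occurrence order). Plus the factor CSV, the scheme YAML, the truth
    record and a manifest; returns the manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset, truth = simulate_dataset(spec)
    scale = spec.digitising_scale

    manifest = {
        "seed": spec.seed,
        "factors_csv": "factors.csv",
        "scheme_yaml": "scheme.yaml",
        "truth_json": "truth.json",
        "operators": [],
    }
    for o, op in enumerate(spec.operators):
        main = dataset.where(operator=op, trial=1)
        shuffle_seed = int(
            np.random.SeedSequence(spec.seed, spawn_key=(o,)).generate_state(1)[0] % (2 ** 31)
        )
        shuffled, key = shuffle_blind(main, shuffle_seed)
        main_name = f"{op.replace('.', '').lower()}_main.tps"
        _write_config_file(shuffled, scale, directory / main_name)

        rep = dataset.where(operator=op).where(
            specimen_id=set(truth.specimens.loc[truth.specimens["replicate"], "specimen_id"])
        )
        rep_name = f"{op.replace('.', '').lower()}_replicates.tps"
        order = np.lexsort((np.arange(rep.n), rep.factors["trial"].to_numpy()))
        _write_config_file(rep.reorder(order), scale, directory / rep_name)
        manifest["operators"].append(
            {"operator": op, "main_tps": main_name, "replicates_tps": rep_name,
             "shuffle_seed": shuffle_seed, "shuffle_key": key.tolist()}
        )

    tps.write_factors(dataset.factors, directory / "factors.csv")
    tps.write_scheme(dataset.scheme, directory / "scheme.yaml")
    truth.to_json(directory / "truth.json")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_config_file(ds: ShapeDataset, scale: float, path) -> None:
    configs = [
        LandmarkConfiguration(
            points=ds.coords[i],
            specimen_id=ds.factors.iloc[i]["specimen_id"],
            group=ds.factors.iloc[i]["group"],
            operator=ds.factors.iloc[i]["operator"],
            trial=int(ds.factors.iloc[i]["trial"]),
            scale=scale,
            image_ref=f"{ds.factors.iloc[i]['specimen_id']}.jpg",
        )
        for i in range(ds.n)
    ]
    tps.write_tps(configs, path)


def read_fixtures(directory):
    """Load fixtures written by :func:`write_fixtures`.

    Returns ``(dataset, truth, manifest)`` with rows sorted by
    (operator, specimen_id, trial).
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    scheme = tps.read_scheme(directory / manifest["scheme_yaml"])
    factors = tps.read_factors(directory / manifest["factors_csv"])
    truth = SyntheticTruth.from_json(directory / manifest["truth_json"])

    configs = []
    for entry in manifest["operators"]:
        op = entry["operator"]
        main = tps.read_tps(directory / entry["main_tps"], operator=op)
        reps = tps.read_tps(directory / entry["replicates_tps"], operator=op)
        main_ids = {c.specimen_id for c in main}
        for c in reps:
            if c.trial == 1 and c.specimen_id in main_ids:
                continue        # trial 1 of the subset already in the main file
            configs.append(c)
        configs.extend(main)
    configs = tps.attach_factors(configs, factors)
    ds = tps.assemble_dataset(configs, scheme)
    order = ds.factors.sort_values(["operator", "specimen_id", "trial"]).index.to_numpy()
    return ds.reorder(order), truth, manifest
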