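"""Seeded synthetic face-like image generation.

The stimuli of the original face-perception studies (3-D reconstructed
faces varying in identity, sex, race and viewpoint; expression photograph
collections) are private, so analyses here run on synthetic grayscale
images that emulate the *statistical* structure those collections provide:

* an **invariant collection** — one image per identity per viewpoint, with
  identities balanced over sex and race; invariant attributes (identity
  morphology, sex, race) are constant within an identity, viewpoint adds
  within-identity variance;
* an **expression collection** — one frontal image per identity per
  expression; expression is rendered as a prototype deformation in a
  latent block orthogonal to the morphology block, with per-image jitter
  and a tunable coupling ``kappa`` that routes expression energy through
  identity-dependent directions.

Every image is a linear map of a latent code through a fixed smooth
(Gaussian-bump) rendering basis, plus pixel noise, clipped to [0, 1] and
quantized to 8-bit levels so that the on-disk PNG round-trip is lossless.

Latent layout (one coordinate space, three orthogonal blocks):

===========  ====  =======================================================
block        dims  contents
===========  ====  =======================================================
morphology   16    14 free identity dims + 1 sex-offset dim + 1 race dim
expression    8    expression prototypes / jitter / coupled component
viewpoint     2    deterministic per-angle shift
===========  ====  =======================================================
"""
from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSpec",
    "LatentFaceCode",
    "IdentityBank",
    "LabeledFaceSet",
    "FaceRenderer",
    "make_identity_bank",
    "render_invariant_dataset",
    "render_expression_dataset",
    "latent_to_image",
    "SEX_LEVELS",
    "RACE_LEVELS",
    "EXPRESSION_LEVELS",
    "DEFAULT_VIEWPOINTS",
    "IMAGE_SHAPE",
    "LATENT_DIM",
]

SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("asian", "caucasian")
EXPRESSION_LEVELS = ("neutral", "anger", "fear", "happiness", "sadness", "surprise")
DEFAULT_VIEWPOINTS = (-10.0, 0.0, 10.0, 20.0, 30.0)
IMAGE_SHAPE = (90, 90)

# latent block layout
N_IDENTITY_DIMS = 14
SEX_DIM = 14
RACE_DIM = 15
M_DIM = 16
E_DIM = 8
V_DIM = 2
LATENT_DIM = M_DIM + E_DIM + V_DIM

LABEL_COLUMNS = ("sample_id", "identity", "sex", "race", "expression", "viewpoint")


@dataclass(frozen=True)
class AttributeSpec:
    """Composition of a generated collection: how many identities, which
    attribute levels, which viewpoints."""

    n_identities: int
    sex_levels: tuple[str, ...] = SEX_LEVELS
    race_levels: tuple[str, ...] = RACE_LEVELS
    expression_levels: tuple[str, ...] = EXPRESSION_LEVELS
    viewpoints: tuple[float, ...] = DEFAULT_VIEWPOINTS

    def __post_init__(self) -> None:
        if self.n_identities < 2:
            raise ValueError("n_identities must be >= 2")
        for name in ("sex_levels", "race_levels", "expression_levels"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise ValueError(f"{name} must be non-empty")
            if len(set(levels)) != len(levels):
                raise ValueError(f"{name} contains duplicates")
        if len(self.sex_levels) > 2 or len(self.race_levels) > 2:
            raise ValueError("at most two sex / race levels are supported")
        unknown = set(self.expression_levels) - set(EXPRESSION_LEVELS)
        if unknown:
            raise ValueError(f"unknown expression levels: {sorted(unknown)}")
        if len(self.viewpoints) == 0:
            raise ValueError("viewpoint list must be non-empty")


@dataclass(frozen=True)
class LatentFaceCode:
    """Latent coordinates of one rendered face."""

    morphology: np.ndarray  # (16,) identity + sex/race offsets
    expression: np.ndarray  # (8,)
    viewpoint: np.ndarray   # (2,)

    def concat(self) -> np.ndarray:
        return np.concatenate([self.morphology, self.expression, self.viewpoint])


@dataclass(frozen=True)
class IdentityBank:
    """One latent morphology per identity plus its invariant labels."""

    spec: AttributeSpec
    morphologies: np.ndarray        # (n_identities, 16)
    sex: tuple[str, ...]
    race: tuple[str, ...]
    seed: int
    effect_size: float

    @property
    def n_identities(self) -> int:
        return self.morphologies.shape[0]


@dataclass
class LabeledFaceSet:
    """Images plus one label row per image; the unit of all training and
    testing.  ``latents`` keeps the generating codes for generator-level
    diagnostics (real datasets loaded from disk have ``latents=None``)."""

    images: np.ndarray            # (n, h, w) float in [0, 1]
    labels: pd.DataFrame
    latents: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, h, w) array")
        if len(self.labels) != self.images.shape[0]:
            raise ValueError(
                f"label rows ({len(self.labels)}) != images ({self.images.shape[0]})"
            )
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise ValueError(f"label table missing columns: {missing}")
        if self.latents is not None and self.latents.shape[0] != self.images.shape[0]:
            raise ValueError("latents row count != image count")

    @property
    def n_samples(self) -> int:
        return self.images.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def take(self, indices: np.ndarray) -> "LabeledFaceSet":
        """Row subset in the given order."""
        indices = np.asarray(indices)
        return LabeledFaceSet(
            images=self.images[indices],
            labels=self.labels.iloc[indices].reset_index(drop=True),
            latents=None if self.latents is None else self.latents[indices],
        )


def _offset_sign(level: str, levels: tuple[str, ...]) -> float:
    # single level -> no offset (the attribute is constant anyway)
    if len(levels) == 1:
        return 0.0
    return -1.0 if level == levels[0] else 1.0


def make_identity_bank(
    spec: AttributeSpec, seed: int, effect_size: float = 2.0
) -> IdentityBank:
    """Draw one latent identity per requested identity, with sex and race
    assigned in the balance the spec requests.

    Identity components are i.i.d. standard normal on the 14 free
    morphology dims; sex and race are fixed unit-vector offsets scaled by
    ``effect_size`` (in units of the within-cell identity s.d., which is 1).

    Raises
    ------
    ValueError
        if ``n_identities`` is not divisible by the number of sex x race
        cells.
    """
    cells = list(itertools.product(spec.sex_levels, spec.race_levels))
    n_cells = len(cells)
    if spec.n_identities % n_cells != 0:
        raise ValueError(
            f"n_identities={spec.n_identities} not divisible into "
            f"{n_cells} sex x race cells "
            f"({spec.n_identities / n_cells:.2f} identities per cell)"
        )
    rng = np.random.default_rng(seed)
    morph = np.zeros((spec.n_identities, M_DIM))
    morph[:, :N_IDENTITY_DIMS] = rng.standard_normal(
        (spec.n_identities, N_IDENTITY_DIMS)
    )
    sex, race = [], []
    for i in range(spec.n_identities):
        s, r = cells[i % n_cells]
        sex.append(s)
        race.append(r)
        morph[i, SEX_DIM] = effect_size * _offset_sign(s, spec.sex_levels)
        morph[i, RACE_DIM] = effect_size * _offset_sign(r, spec.race_levels)
    return IdentityBank(
        spec=spec,
        morphologies=morph,
        sex=tuple(sex),
        race=tuple(race),
        seed=seed,
        effect_size=effect_size,
    )


class FaceRenderer:
    """Fixed, seeded linear rendering basis from latent space to pixels.

    Each latent dimension maps to one smooth image component: a 2-D
    Gaussian bump placed on a jittered grid, mean-removed and L2
    normalized, then scaled by a per-dimension gain.  Gains decay
    geometrically inside the identity and expression blocks so that the
    pixel-variance spectrum of the generated collections resembles real
    face sets (a few dominant morphology directions, then a tail), which
    is what makes the downstream PCA stage behave realistically at
    10-40 retained components.

    The renderer also owns the expression prototypes (fixed unit
    directions in the expression block scaled to ``expression_scale``)
    and the identity->expression coupling map used when ``kappa > 0``.
    """

    def __init__(
        self,
        seed: int = 0,
        image_shape: tuple[int, int] = IMAGE_SHAPE,
        identity_gain: float = 1.0,
        identity_decay: float = 0.9,
        offset_gain: float = 1.0,
        expression_gain: float = 1.0,
        expression_decay: float = 1.0,
        viewpoint_gain: float = 0.6,
        expression_scale: float = 3.0,
        expression_jitter: float = 0.25,
        expression_overlap: float = 0.15,
        expression_dedicated: float = 1.0,
        session_morph: float = 0.0,
        session_offset: float = 0.0,
        viewpoint_morph: float = 4.0,
        viewpoint_offset_morph: float = 3.0,
        quantize: bool = True,
    ) -> None:
        self.seed = int(seed)
        self.image_shape = tuple(image_shape)
        self.expression_scale = float(expression_scale)
        self.expression_jitter = float(expression_jitter)
        self.expression_overlap = float(expression_overlap)
        self.session_morph = float(session_morph)
        self.session_offset = float(session_offset)
        self.viewpoint_morph = float(viewpoint_morph)
        self.viewpoint_offset_morph = float(viewpoint_offset_morph)
        self.quantize = bool(quantize)
        rng = np.random.default_rng([self.seed, 0xFACE])
        h, w = self.image_shape
        n_pix = h * w

        # bump centers: jittered 6 x 5 grid, shuffled, one per latent dim
        gy, gx = np.meshgrid(
            np.linspace(0.15 * h, 0.85 * h, 6), np.linspace(0.15 * w, 0.85 * w, 5),
            indexing="ij",
        )
        centers = np.column_stack([gy.ravel(), gx.ravel()])
        centers += rng.uniform(-0.04 * h, 0.04 * h, size=centers.shape)
        rng.shuffle(centers)
        centers = centers[:LATENT_DIM]
        sigmas = rng.uniform(0.09 * h, 0.18 * h, size=LATENT_DIM)

        yy, xx = np.mgrid[0:h, 0:w]
        cols = np.empty((n_pix, LATENT_DIM))
        for j in range(LATENT_DIM):
            bump = np.exp(
                -(((yy - centers[j, 0]) ** 2) + ((xx - centers[j, 1]) ** 2))
                / (2.0 * sigmas[j] ** 2)
            ).ravel()
            bump -= bump.mean()
            cols[:, j] = bump / np.linalg.norm(bump)
        # orthonormalize so latent dims map to uncorrelated pixel
        # directions (bumps overlap spatially; QR keeps each column a
        # smooth mixture of nearby bumps while removing the overlap)
        cols, _ = np.linalg.qr(cols)
        cols *= np.sign(np.sum(cols, axis=0) + 1e-12)

        gains = np.empty(LATENT_DIM)
        gains[:N_IDENTITY_DIMS] = identity_gain * identity_decay ** np.arange(
            N_IDENTITY_DIMS
        )
        gains[SEX_DIM] = offset_gain
        gains[RACE_DIM] = offset_gain
        gains[M_DIM : M_DIM + E_DIM] = expression_gain * expression_decay ** np.arange(
            E_DIM
        )
        gains[M_DIM + E_DIM :] = viewpoint_gain
        basis = cols * gains  # (n_pix, LATENT_DIM)

        # Expression deformations act largely on the same facial-surface
        # components that carry morphology (mouth/eye regions vary with
        # identity too): each expression dim renders as a mixture of its
        # own dedicated surface component (weight ``expression_dedicated``)
        # and a fixed combination of the free-morphology columns (weight
        # ``expression_overlap``).  The mixing map is global
        # (identity-independent), so the expression component still
        # carries no identity information at kappa = 0.
        share = rng.standard_normal((N_IDENTITY_DIMS, E_DIM)) / np.sqrt(
            N_IDENTITY_DIMS
        )
        basis[:, M_DIM : M_DIM + E_DIM] = (
            expression_dedicated * basis[:, M_DIM : M_DIM + E_DIM]
            + expression_overlap * basis[:, :N_IDENTITY_DIMS] @ share
        )
        self.basis = basis

        # Pose-morphology interaction scales: a viewpoint change perturbs
        # the whole morphology-block appearance (3-D pose changes every
        # shape cue), proportionally to the off-frontal angle, with one
        # scale for the free identity dims and one for the sex/race
        # appearance dims.  The perturbation direction is a deterministic
        # function of (morphology, viewpoint) -- see ``pose_jitter`` --
        # so identical latent codes still render to identical images.
        pose_scale = np.full(M_DIM, self.viewpoint_morph)
        pose_scale[SEX_DIM] = self.viewpoint_offset_morph
        pose_scale[RACE_DIM] = self.viewpoint_offset_morph
        self.pose_scale = pose_scale

        base = np.exp(
            -(((yy - 0.5 * h) ** 2) + ((xx - 0.5 * w) ** 2)) / (2.0 * (0.33 * h) ** 2)
        )
        self.base_face = (0.30 + 0.40 * base).ravel()

        # expression prototypes: fixed unit directions scaled to a common norm
        proto = rng.standard_normal((len(EXPRESSION_LEVELS), E_DIM))
        proto /= np.linalg.norm(proto, axis=1, keepdims=True)
        self.expression_prototypes = proto * self.expression_scale
        # identity -> expression coupling map (kappa > 0)
        self.coupling_map = rng.standard_normal((E_DIM, N_IDENTITY_DIMS)) / np.sqrt(
            N_IDENTITY_DIMS
        )

    # -- rendering ---------------------------------------------------------

    def prototype(self, expression: str) -> np.ndarray:
        try:
            idx = EXPRESSION_LEVELS.index(expression)
        except ValueError:
            raise ValueError(f"unknown expression {expression!r}") from None
        return self.expression_prototypes[idx]

    def coupled_direction(self, morphology: np.ndarray) -> np.ndarray:
        """Identity-dependent unit direction in the expression block."""
        v = self.coupling_map @ morphology[:N_IDENTITY_DIMS]
        n = np.linalg.norm(v)
        if n == 0.0:
            v = np.zeros(E_DIM)
            v[0] = 1.0
            return v
        return v / n

    def pose_axis(self, morphology: np.ndarray) -> np.ndarray:
        """Per-face pose-appearance axis: as a 3-D head rotates, its
        rendered morphology drifts along one face-specific direction.
        The axis is a deterministic draw keyed on (renderer seed,
        morphology), so identical latent codes share their axis."""
        key = [
            self.seed,
            zlib.crc32(np.ascontiguousarray(morphology, dtype=float).tobytes()),
        ]
        return np.random.default_rng(key).standard_normal(M_DIM)

    def pose_jitter(self, morphology: np.ndarray, angle: float) -> np.ndarray:
        """Morphology-appearance perturbation at one viewpoint.

        The whole morphology block drifts along the face's fixed pose
        axis, scaled by angle/30 (zero at frontal), by
        ``viewpoint_morph`` on the free identity dims and by
        ``viewpoint_offset_morph`` on the sex/race appearance dims: a
        rotating 3-D head changes every shape cue coherently, including
        how male/female or Asian/Caucasian it looks.  Deterministic in
        (renderer seed, morphology, angle)."""
        a = float(angle) / 30.0
        if a == 0.0:
            return np.zeros(M_DIM)
        return a * self.pose_scale * self.pose_axis(morphology)

    def render(self, code: np.ndarray, noise: np.ndarray | None = None) -> np.ndarray:
        """Map a concatenated latent code to a (h, w) image in [0, 1]."""
        code = np.asarray(code, dtype=float).ravel()
        if code.shape[0] != LATENT_DIM:
            raise ValueError(
                f"latent code has dimension {code.shape[0]}, basis expects {LATENT_DIM}"
            )
        img = self.base_face + self.basis @ code
        if noise is not None:
            img = img + noise.ravel()
        img = np.clip(img, 0.0, 1.0)
        if self.quantize:
            img = np.round(img * 255.0) / 255.0
        return img.reshape(self.image_shape)


def latent_to_image(code: LatentFaceCode | np.ndarray, basis: FaceRenderer) -> np.ndarray:
    """Render a single latent code through a fixed basis (no pixel noise)."""
    if isinstance(code, LatentFaceCode):
        code = code.concat()
    return basis.render(code)


def _viewpoint_component(angle: float) -> np.ndarray:
    a = angle / 30.0
    return np.array([a, a * a])


def render_invariant_dataset(
    bank: IdentityBank,
    viewpoints: tuple[float, ...] | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    renderer: FaceRenderer | None = None,
) -> LabeledFaceSet:
    """One image per identity per viewpoint; expression constant ("neutral").

    Viewpoint is modeled as a deterministic latent shift (adds
    within-identity variance without geometric rotation).
    """
    if bank.n_identities == 0:
        raise ValueError("identity bank is empty")
    if viewpoints is None:
        viewpoints = bank.spec.viewpoints
    if len(viewpoints) == 0:
        raise ValueError("viewpoint list must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if renderer is None:
        renderer = FaceRenderer(seed=seed)
    rng = np.random.default_rng([seed, 1])
    h, w = renderer.image_shape
    n = bank.n_identities * len(viewpoints)
    images = np.empty((n, h, w))
    latents = np.empty((n, LATENT_DIM))
    rows = []
    i = 0
    for ident in range(bank.n_identities):
        for vp in viewpoints:
            morph = bank.morphologies[ident] + renderer.pose_jitter(
                bank.morphologies[ident], vp
            )
            code = np.concatenate(
                [morph, np.zeros(E_DIM), _viewpoint_component(vp)]
            )
            noise = rng.normal(0.0, noise_sd, h * w) if noise_sd > 0 else None
            images[i] = renderer.render(code, noise)
            latents[i] = code
            rows.append(
                {
                    "sample_id": f"{i:06d}",
                    "identity": f"id{ident:04d}",
                    "sex": bank.sex[ident],
                    "race": bank.race[ident],
                    "expression": "neutral",
                    "viewpoint": float(vp),
                }
            )
            i += 1
    return LabeledFaceSet(images=images, labels=pd.DataFrame(rows), latents=latents)


def render_expression_dataset(
    bank: IdentityBank,
    expressions: tuple[str, ...] | None = None,
    kappa: float = 0.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    renderer: FaceRenderer | None = None,
) -> LabeledFaceSet:
    """One frontal image per identity per expression.

    The expression deformation for identity *i*, expression *x* is

        s_x * ( sqrt(1 - kappa) * u_x  +  sqrt(kappa) * u_i )  +  jitter

    where ``u_x`` is the expression prototype direction, ``s_x`` its norm,
    and ``u_i`` a fixed identity-dependent unit direction in the
    expression block.  At ``kappa = 0`` the expression component carries
    no identity/sex/race information; at ``kappa = 1`` the deformation
    direction differs across identities.  Jitter is isotropic with
    per-dimension s.d. ``expression_jitter * s_x`` (0.25 of the
    prototype norm by default), so expressed faces scatter broadly
    around their prototype and expression discrimination is markedly
    harder than the invariant tasks.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    if expressions is None:
        expressions = bank.spec.expression_levels
    if len(expressions) == 0:
        raise ValueError("expression list must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if renderer is None:
        renderer = FaceRenderer(seed=seed)
    rng = np.random.default_rng([seed, 2])
    h, w = renderer.image_shape
    n = bank.n_identities * len(expressions)
    images = np.empty((n, h, w))
    latents = np.empty((n, LATENT_DIM))
    rows = []
    i = 0
    # per-image "session" variability: photographs of one person differ
    # in hairline, lighting and pose micro-changes, which perturb the
    # rendered morphology (free dims and sex/race appearance dims alike)
    session_sd = np.full(M_DIM, renderer.session_morph)
    session_sd[SEX_DIM] = renderer.session_offset
    session_sd[RACE_DIM] = renderer.session_offset
    for ident in range(bank.n_identities):
        u_i = renderer.coupled_direction(bank.morphologies[ident])
        for expr in expressions:
            proto = renderer.prototype(expr)
            s = np.linalg.norm(proto)
            direction = np.sqrt(1.0 - kappa) * proto + np.sqrt(kappa) * s * u_i
            jitter_sd = renderer.expression_jitter * s  # per-dim s.d.
            jitter = rng.normal(0.0, jitter_sd, E_DIM)
            e_comp = direction + jitter
            morph = bank.morphologies[ident] + session_sd * rng.standard_normal(M_DIM)
            code = np.concatenate([morph, e_comp, np.zeros(V_DIM)])
            noise = rng.normal(0.0, noise_sd, h * w) if noise_sd > 0 else None
            images[i] = renderer.render(code, noise)
            latents[i] = code
            rows.append(
                {
                    "sample_id": f"{i:06d}",
                    "identity": f"id{ident:04d}",
                    "sex": bank.sex[ident],
                    "race": bank.race[ident],
                    "expression": expr,
                    "viewpoint": 0.0,
                }
            )
            i += 1
    return LabeledFaceSet(images=images, labels=pd.DataFrame(rows), latents=latents)
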