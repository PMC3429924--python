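"""Branching-growth simulator of chromosome loss in the wing disc.

The generative model: at treatment the disc holds ``n0`` cells, each still
carrying the rescuing Y chromosome. Cells then complete ``rounds``
synchronous divisions. At every division of an unlabeled cell the Y
chromosome is lost with probability ``p_loss``; the loss affects exactly one
of the two daughters, which founds a labeled (mwh) clone, while its sister
stays unlabeled. Labeled cells keep dividing but cannot lose the chromosome
again. A clone founded at round ``r`` therefore reaches 2**(R - r) cells at
the end of proliferation, which is the origin of the size-class bookkeeping
(a size class counts the minimum number of divisions since the loss event).

Regeneration mode emulates cytotoxic treatments (X-rays, colchicine): a
``death_fraction`` of treatment-time cells is removed and every survivor,
labeled or not, performs ``extra_rounds`` compensatory divisions, producing
the oversized clones seen after such treatments.

After growth, roughly half of the disc (``blade_fraction``) is sampled into
the screened blade area, embedded on two rectangular surface lattices with
each clone as one connected patch, and rendered into trichome phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .records import CELL_COLUMNS, WingRecord

__all__ = [
    "LineagePopulation",
    "PlacementError",
    "simulate_disc",
    "embed_wing",
    "render_trichomes",
    "simulate_wing",
    "simulate_cohort",
]


class PlacementError(RuntimeError):
    """Clones cannot be placed on the lattice at the requested gap/density."""


@dataclass
class LineagePopulation:
    """Final disc population with per-cell ground truth.

    All arrays share one length (the number of cells at the end of
    proliferation). ``clone_id`` is -1 for unlabeled cells; every labeled
    cell's id traces back to exactly one loss event, and ``founding_round``
    records the 1-based division round of that event.
    """

    lineage_id: np.ndarray
    labeled: np.ndarray
    clone_id: np.ndarray
    founding_round: np.ndarray
    n_loss_events: int
    total_rounds: int

    def __len__(self) -> int:
        return len(self.labeled)

    @property
    def n_labeled(self) -> int:
        return int(self.labeled.sum())

    def clone_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.clone_id[self.labeled], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def clone_founding_rounds(self) -> dict[int, int]:
        mask = self.labeled
        ids = self.clone_id[mask]
        rounds = self.founding_round[mask]
        first = {}
        for cid, r in zip(ids.tolist(), rounds.tolist()):
            first.setdefault(cid, r)
        return first


def simulate_disc(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> LineagePopulation:
    """Grow the disc population through synchronous division rounds.

    Returns the final population with ground-truth labels, clone ids and
    founding rounds. Validation of ``p_loss`` and the cell-count safety cap
    happen in :class:`~wingmosaic.config.SimulationConfig`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_dead = int(round(config.death_fraction * config.n0))
    n_start = config.n0 - n_dead
    if n_start < 1:
        raise ValueError("death_fraction leaves no surviving cells")

    lineage = np.arange(n_start, dtype=np.int64)
    labeled = np.zeros(n_start, dtype=bool)
    clone_id = np.full(n_start, -1, dtype=np.int64)
    founding = np.full(n_start, -1, dtype=np.int16)
    next_clone = 0

    for r in range(1, config.total_rounds + 1):
        loss = (~labeled) & (rng.random(len(labeled)) < config.p_loss)
        n_new = int(loss.sum())
        # daughter A inherits the mother state unchanged
        a_lineage, a_labeled = lineage, labeled
        a_clone, a_founding = clone_id, founding
        # daughter B is labeled wherever a loss event occurred
        b_labeled = labeled | loss
        b_clone = clone_id.copy()
        b_founding = founding.copy()
        if n_new:
            b_clone[loss] = np.arange(next_clone, next_clone + n_new)
            b_founding[loss] = r
            next_clone += n_new
        lineage = np.concatenate([a_lineage, lineage])
        labeled = np.concatenate([a_labeled, b_labeled])
        clone_id = np.concatenate([a_clone, b_clone])
        founding = np.concatenate([a_founding, b_founding])

    return LineagePopulation(
        lineage_id=lineage,
        labeled=labeled,
        clone_id=clone_id,
        founding_round=founding,
        n_loss_events=next_clone,
        total_rounds=config.total_rounds,
    )


def _square_patch(origin_x: int, origin_y: int, side: int, size: int) -> np.ndarray:
    """Row-major fill of a side x side square: connected for any size."""
    j = np.arange(size)
    return np.column_stack([origin_x + j % side, origin_y + j // side])


def _place_surface(
    count: int,
    clone_sizes: list[tuple[int, int]],
    gap: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Lay out one surface.

    Returns (coords, clone_assignment): ``coords`` is (count, 2); the first
    rows hold clone-member coordinates in the order of ``clone_sizes``
    (``clone_assignment`` maps each row to a clone id, -1 for unlabeled).
    Clone patches are connected squares placed on a slot grid so that any
    two patches are separated by at least ``gap`` intervening lattice cells
    (Chebyshev sense).
    """
    width = int(np.ceil(np.sqrt(count)))
    height = int(np.ceil(count / width))
    full_rows = count // width

    all_idx = np.arange(count)
    all_coords = np.column_stack([all_idx % width, all_idx // width])

    if not clone_sizes:
        return all_coords, np.full(count, -1, dtype=np.int64)

    sides = [int(np.ceil(np.sqrt(s))) for _, s in clone_sizes]
    slot = max(sides) + gap
    slots_x = width // slot
    slots_y = full_rows // slot
    n_slots = slots_x * slots_y
    if n_slots < len(clone_sizes):
        raise PlacementError(
            f"cannot place {len(clone_sizes)} clones with gap {gap} on a "
            f"{width}x{height} surface of {count} cells ({n_slots} slots)"
        )

    slot_order = rng.permutation(n_slots)[: len(clone_sizes)]
    clone_coords = []
    assignment = []
    for (cid, size), side, s in zip(clone_sizes, sides, slot_order):
        ox = int(s % slots_x) * slot
        oy = int(s // slots_x) * slot
        patch = _square_patch(ox, oy, side, size)
        clone_coords.append(patch)
        assignment.append(np.full(size, cid, dtype=np.int64))
    clone_coords = np.concatenate(clone_coords)
    assignment = np.concatenate(assignment)

    taken = set(map(tuple, clone_coords.tolist()))
    free_mask = np.array(
        [tuple(c) not in taken for c in all_coords.tolist()], dtype=bool
    )
    free = all_coords[free_mask]
    n_unlabeled = count - len(clone_coords)
    if len(free) < n_unlabeled:  # pragma: no cover - guarded by slot check
        raise PlacementError("clone patches exceed the surface area")
    coords = np.concatenate([clone_coords, free[:n_unlabeled]])
    clone_assignment = np.concatenate(
        [assignment, np.full(n_unlabeled, -1, dtype=np.int64)]
    )
    return coords, clone_assignment


def embed_wing(
    pop: LineagePopulation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    wing_id: str = "w0",
    group: str = "sim",
) -> WingRecord:
    """Sample the blade and lay cells out on the two surface lattices.

    A ``blade_fraction`` sample of the final population (uniform, without
    replacement) is truncated or padded with plain unlabeled cells to exactly
    ``screened_cells``; every surviving clone is assigned wholly to one
    surface and placed as a connected patch, distinct patches separated by
    at least ``clone_gap`` unlabeled cells. Trichome fields are left
    unrendered (count 0).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    total = len(pop)
    n_sample = int(round(config.blade_fraction * total))
    n_sample = max(min(n_sample, total), 0)
    idx = rng.choice(total, size=n_sample, replace=False)
    if n_sample > config.screened_cells:
        idx = idx[rng.permutation(n_sample)[: config.screened_cells]]
    labeled = pop.labeled[idx]
    clone_ids = pop.clone_id[idx]
    n_pad = config.screened_cells - len(idx)

    # surviving clones, deterministic order
    surv_ids, surv_sizes = np.unique(clone_ids[labeled], return_counts=True)
    surface_of = {
        int(cid): ("D", "V")[int(rng.integers(2))] for cid in surv_ids.tolist()
    }

    n_dorsal = config.screened_cells - config.screened_cells // 2
    per_surface = {"D": n_dorsal, "V": config.screened_cells // 2}
    frames = []
    for surface in ("D", "V"):
        clones_here = [
            (int(cid), int(sz))
            for cid, sz in zip(surv_ids.tolist(), surv_sizes.tolist())
            if surface_of[int(cid)] == surface
        ]
        n_labeled_here = sum(sz for _, sz in clones_here)
        count = per_surface[surface]
        if n_labeled_here > count:
            raise PlacementError(
                f"surface {surface}: {n_labeled_here} labeled cells exceed "
                f"{count} available positions"
            )
        coords, assignment = _place_surface(count, clones_here, config.clone_gap, rng)
        frames.append(
            pd.DataFrame(
                {
                    "surface": surface,
                    "x": coords[:, 0],
                    "y": coords[:, 1],
                    "n_trichomes": 0,
                    "orientations": [()] * count,
                    "true_label": (assignment >= 0).astype(np.int64),
                    "true_clone_id": assignment,
                }
            )
        )
    cells = pd.concat(frames, ignore_index=True)
    assert len(cells) == config.screened_cells
    # padding cells are unlabeled by construction; nothing further to do
    _ = n_pad
    return WingRecord(wing_id=wing_id, group=group, cells=cells[CELL_COLUMNS].copy())


def render_trichomes(
    wing: WingRecord,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> WingRecord:
    """Render trichome phenotypes onto an embedded wing.

    Wild-type cells carry a single trichome with one orientation sector;
    labeled cells carry 2-5 trichomes (uniform over
    ``[trichome_min, trichome_max]``) spanning at least two distinct
    orientation sectors — the divergent-polarity mwh phenotype. A
    ``noise_rate`` fraction of wild-type cells is rendered with two
    trichomes in the *same* sector, mimicking occasional doubled hairs that
    a correct caller must not score as mwh.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    out = wing.copy()
    cells = out.cells
    n = len(cells)
    labeled = (cells["true_label"] == 1).to_numpy()

    counts = np.ones(n, dtype=np.int64)
    counts[labeled] = rng.integers(
        config.trichome_min, config.trichome_max + 1, size=int(labeled.sum())
    )

    noise = (~labeled) & (rng.random(n) < config.noise_rate)
    counts[noise] = 2

    base = rng.integers(0, 8, size=n)
    orientations: list[tuple[int, ...]] = [()] * n
    wt_idx = np.flatnonzero(~labeled & ~noise)
    for i in wt_idx.tolist():
        orientations[i] = (int(base[i]),)
    for i in np.flatnonzero(noise).tolist():
        orientations[i] = (int(base[i]), int(base[i]))
    lab_idx = np.flatnonzero(labeled)
    if len(lab_idx):
        # second trichome forced into a different sector; the rest are free
        offsets = rng.integers(1, 8, size=len(lab_idx))
        for i, off in zip(lab_idx.tolist(), offsets.tolist()):
            k = int(counts[i])
            first = int(base[i])
            rest = rng.integers(0, 8, size=k - 2).tolist() if k > 2 else []
            orientations[i] = tuple([first, (first + off) % 8] + [int(v) for v in rest])

    cells["n_trichomes"] = counts
    cells["orientations"] = orientations
    return out


def simulate_wing(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    wing_id: str = "w0",
    group: str = "sim",
) -> WingRecord:
    """Full single-wing pipeline: grow, embed, render."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = simulate_disc(config, rng)
    wing = embed_wing(pop, config, rng, wing_id=wing_id, group=group)
    return render_trichomes(wing, config, rng)


def simulate_cohort(
    config: SimulationConfig,
    n_wings: int,
    group: str = "sim",
    seed: int | None = None,
) -> list[WingRecord]:
    """Simulate ``n_wings`` independent wings of one treatment group.

    Each wing gets its own child stream spawned from one seed sequence, so
    the cohort is reproducible as a whole and wing order is immaterial.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    wings = []
    for i, child in enumerate(root.spawn(n_wings)):
        rng = np.random.default_rng(child)
        wings.append(
            simulate_wing(config, rng, wing_id=f"{group}_w{i:04d}", group=group)
        )
    return wings
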