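"""Building-block screening and combinatorial product enumeration.

Pipeline per reactant slot: pattern matching first (the "compatible
reactant" accounting stage), then logic evaluation per match binding.  A
block passes a slot when at least one binding survives (not killed, final
rating > 0); the highest-rated surviving binding drives product generation,
ties broken by lowest matched-atom indices.

The Cartesian product of surviving blocks is enumerated lazily in file
order; a combination's rating is the minimum over its slot ratings; the
mapped reaction is applied site-directedly at each chosen binding;
duplicates collapse by product InChIKey when deduplication is on.
"""

from __future__ import annotations

import itertools
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from rdkit import Chem
from rdkit.Chem import AllChem

from .logic_eval import LogicOutcome, run_program
from .pattern_engine import (
    GroupLibrary, MatchBinding, StructureError, compile_pattern, find_matches,
    mol_from_smiles,
)
from .transform_model import Transform

__all__ = [
    "BuildingBlock", "ProductRecord", "GenerationOptions", "SlotEval",
    "screen_blocks", "evaluate_slot", "apply_reaction", "enumerate_products",
    "combination_rating",
]

log = logging.getLogger(__name__)


@dataclass
class BuildingBlock:
    id: str
    smiles: str
    mol: Chem.Mol = None

    def __post_init__(self):
        if self.mol is None:
            self.mol = mol_from_smiles(self.smiles, self.id)


@dataclass
class ProductRecord:
    smiles: str
    reactant_ids: tuple[str, ...]
    rating: int
    killed: bool
    ghosts: tuple[str, ...]
    inchikey: str


@dataclass
class GenerationOptions:
    hide_ghosts: bool = False
    kill_low_rated: bool = True
    inchikey_only: bool = False
    dedupe: bool = True
    max_products: Optional[int] = None
    random_seed: int = 0


def combination_rating(slot_ratings: list[int]) -> int:
    """A combination is as favorable as its worst slot."""
    if not slot_ratings:
        raise ValueError("combination_rating needs at least one slot rating")
    for r in slot_ratings:
        if not 0 <= r <= 100:
            raise ValueError(f"slot rating {r} outside [0, 100]")
    return min(slot_ratings)


# ---------------------------------------------------------------------------
# screening & per-slot logic


def screen_blocks(t: Transform, slot: int, blocks: Iterable[BuildingBlock],
                  ) -> list[tuple[BuildingBlock, list[MatchBinding]]]:
    """Blocks with >= 1 match of the slot's keying pattern (logic NOT yet
    applied).  Unparseable blocks are counted and skipped, not fatal."""
    pattern = t.slot_pattern(slot)
    out = []
    skipped = 0
    for block in blocks:
        try:
            mol = block.mol if block.mol is not None \
                else mol_from_smiles(block.smiles, block.id)
        except StructureError as exc:
            skipped += 1
            log.warning("skipping block: %s", exc)
            continue
        bindings = find_matches(pattern, mol)
        if bindings:
            out.append((block, bindings))
    if skipped:
        log.info("slot %d: skipped %d unparseable block(s)", slot + 1, skipped)
    return out


@dataclass
class SlotEval:
    """Logic results for one block in one slot."""

    block: BuildingBlock
    outcomes: list[tuple[MatchBinding, LogicOutcome]]

    @property
    def surviving(self) -> list[tuple[MatchBinding, LogicOutcome]]:
        return [(b, o) for b, o in self.outcomes if o.rating.retained]

    def best(self, require_survivor: bool) -> Optional[tuple[MatchBinding, LogicOutcome]]:
        pool = self.surviving if require_survivor else self.outcomes
        if not pool:
            return None
        # highest rating wins; ties -> lowest matched atom indices
        return min(pool, key=lambda bo: (-bo[1].rating.value,
                                         tuple(sorted(bo[0].onpath_atoms))))


def evaluate_slot(t: Transform, slot: int,
                  screened: list[tuple[BuildingBlock, list[MatchBinding]]],
                  group_library: Optional[GroupLibrary] = None) -> list[SlotEval]:
    program = t.slot_logic(slot)
    return [
        SlotEval(block, [(b, run_program(program, b, group_library))
                         for b in bindings])
        for block, bindings in screened
    ]


# ---------------------------------------------------------------------------
# reaction application


class _ReactionCache:
    def __init__(self, t: Transform):
        from rdkit import rdBase
        core = strip_smirks_extensions(t.smirks)
        with rdBase.BlockLogs():
            # reactant-only maps (leaving groups) trigger a benign warning
            self.rxn = AllChem.ReactionFromSmarts(core)
        if self.rxn is None:
            raise ValueError(f"unparseable reaction SMARTS {t.smirks!r}")


def strip_smirks_extensions(smirks: str) -> str:
    """Reaction templates must be standard SMIRKS; extension tokens live only
    in keying patterns, so stripping is a no-op for well-formed transforms."""
    from .pattern_engine import _strip_extensions
    if ">>" not in smirks:
        return smirks
    lhs, _, rhs = smirks.partition(">>")
    return _strip_extensions(lhs)[0] + ">>" + _strip_extensions(rhs)[0]


def _protected_copy(mol: Chem.Mol, keep: frozenset[int]) -> Chem.Mol:
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        if atom.GetIdx() not in keep:
            atom.SetProp("_protected", "1")
    return out


def apply_reaction(t: Transform, chosen: list[tuple[BuildingBlock, MatchBinding]],
                   rxn=None) -> list[str]:
    """Apply the mapped reaction at the chosen binding of each reactant.

    All atoms outside each binding are protected so the reaction fires only
    at the logic-approved site.  Returns canonical product SMILES (unique
    within the combination); products failing valence sanitization are
    excluded with a logged reason.
    """
    if rxn is None:
        rxn = _ReactionCache(t).rxn
    reactants = tuple(
        _protected_copy(block.mol, binding.onpath_atoms)
        for block, binding in chosen)
    products: list[str] = []
    seen: set[str] = set()
    for product_set in rxn.RunReactants(reactants):
        frags = []
        ok = True
        for mol in product_set:
            try:
                Chem.SanitizeMol(mol)
            except Exception as exc:  # rdkit raises several sanitize errors
                log.debug("product failed sanitization (%s): %s",
                          "+".join(b.id for b, _ in chosen), exc)
                ok = False
                break
            frags.append(Chem.MolToSmiles(mol))
        if not ok:
            continue
        smiles = ".".join(frags)
        if smiles not in seen:
            seen.add(smiles)
            products.append(smiles)
    return products


# ---------------------------------------------------------------------------
# enumeration


def _slot_survivors(t: Transform, blocks_by_slot, opts, group_library):
    """Screen + evaluate every slot; returns per-slot lists of
    (block, best_binding, best_outcome)."""
    survivors = []
    for slot, blocks in enumerate(blocks_by_slot):
        screened = screen_blocks(t, slot, blocks)
        evaluated = evaluate_slot(t, slot, screened, group_library)
        slot_list = []
        for ev in evaluated:
            best = ev.best(require_survivor=opts.kill_low_rated)
            if best is None:
                continue
            slot_list.append((ev.block, best[0], best[1]))
        survivors.append(slot_list)
    return survivors


def enumerate_products(t: Transform,
                       blocks_by_slot: list[list[BuildingBlock]],
                       opts: Optional[GenerationOptions] = None,
                       group_library: Optional[GroupLibrary] = None,
                       ) -> Iterator[ProductRecord]:
    """Lazily enumerate rated products over the Cartesian product of
    surviving blocks, outer slot first, in file order."""
    opts = opts or GenerationOptions()
    if len(blocks_by_slot) != t.num_slots:
        raise ValueError(
            f"transform has {t.num_slots} reactant slot(s) but "
            f"{len(blocks_by_slot)} block list(s) were supplied")
    survivors = _slot_survivors(t, blocks_by_slot, opts, group_library)
    rxn = _ReactionCache(t).rxn
    yield from _enumerate_from_survivors(t, survivors, opts, rxn)


def _enumerate_from_survivors(t, survivors, opts, rxn,
                              seen: Optional[set[str]] = None,
                              emitted: Optional[list[int]] = None,
                              ) -> Iterator[ProductRecord]:
    seen = set() if seen is None else seen
    count = 0
    for combo in itertools.product(*survivors):
        ratings = [outcome.rating.value for _, _, outcome in combo]
        killed = any(outcome.rating.killed for _, _, outcome in combo)
        rating = combination_rating(ratings)
        if opts.kill_low_rated and (killed or rating <= 0):
            continue
        chosen = [(block, binding) for block, binding, _ in combo]
        ghosts = list(t.ghost_templates)
        for _, _, outcome in combo:
            ghosts.extend(outcome.ghosts)
        for smiles in apply_reaction(t, chosen, rxn=rxn):
            inchikey = Chem.MolToInchiKey(Chem.MolFromSmiles(smiles))
            if opts.dedupe:
                if inchikey in seen:
                    continue
                seen.add(inchikey)
            yield ProductRecord(
                smiles=smiles,
                reactant_ids=tuple(block.id for block, _ in chosen),
                rating=rating,
                killed=killed,
                ghosts=tuple(ghosts),
                inchikey=inchikey,
            )
            count += 1
            if opts.max_products is not None and count >= opts.max_products:
                return


def enumerate_products_partitioned(
        t: Transform,
        blocks_by_slot: list[list[BuildingBlock]],
        opts: Optional[GenerationOptions] = None,
        group_library: Optional[GroupLibrary] = None,
        workers: int = 1) -> list[ProductRecord]:
    """Partition slot-1 blocks into `workers` ranges, enumerate each range on
    a thread pool, and merge in serial order; after dedupe the result equals
    the serial run."""
    opts = opts or GenerationOptions()
    if workers <= 1:
        return list(enumerate_products(t, blocks_by_slot, opts, group_library))
    survivors = _slot_survivors(t, blocks_by_slot, opts, group_library)
    rxn = _ReactionCache(t).rxn
    first = survivors[0]
    chunk = max(1, -(-len(first) // workers))
    parts = [first[i:i + chunk] for i in range(0, len(first), chunk)]
    part_opts = GenerationOptions(
        hide_ghosts=opts.hide_ghosts, kill_low_rated=opts.kill_low_rated,
        inchikey_only=opts.inchikey_only, dedupe=False, max_products=None,
        random_seed=opts.random_seed)

    def run_part(part):
        return list(_enumerate_from_survivors(
            t, [part] + survivors[1:], part_opts, rxn))

    with ThreadPoolExecutor(max_workers=workers) as pool:
        chunks = list(pool.map(run_part, parts))

    merged: list[ProductRecord] = []
    seen: set[str] = set()
    for records in chunks:
        for rec in records:
            if opts.dedupe:
                if rec.inchikey in seen:
                    continue
                seen.add(rec.inchikey)
            merged.append(rec)
            if opts.max_products is not None and len(merged) >= opts.max_products:
                return merged
    return merged
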