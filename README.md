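# rxnforge

A chemist-writable reaction-transform language and a combinatorial
virtual-library generation engine, built on RDKit.

A **transform** codifies one reaction type: an atom-mapped reaction pattern
(SMIRKS), optional quality metrics, and one IF-THEN **logic program** per
reactant slot. The engine screens building blocks (TSV of `id<TAB>SMILES`)
against each slot's keying pattern, evaluates the logic on every match,
enumerates the Cartesian product of surviving blocks, applies the reaction
site-directedly, and emits rated, ghost-balanced products as SDF / CSV /
InChIKey lists.

## The logic language

Statements follow an IFTTT-style template, evaluated per pattern match:

```text
if <subject> <relation> <predicate> [<where>] then <action>
```

* **subjects** — `atom 1`, `alpha to atom 2`,
  `bond between atom 2 and atom 3`, `molecule`, or a loop variable;
  several subjects combine with `and`/`or`.
* **relations** — `is`/`are` for qualitative predicates, `has`/`have` for
  quantitative ones.
* **predicates** — qualitative (`aromatic`, `in ring`, `primary center`,
  `carbon atom`, `the origin of amine1 group`, ...) or quantitative
  (`at least 1 positive charge`, `at most 2 chlorines`, `one hydrogen`);
  a bare count means *exactly*; number words `one`..`ten` are accepted;
  `not` negates a predicate.
* **where** — `offpath` / `onpath` restricts objects relative to the keying
  pattern match (off-path = not part of the matched substructure).
* **actions** — `kill`, `raise rating <magnitude>`,
  `lower rating <magnitude>` with magnitudes
  `slightly`/`moderately`/`strongly`/`severely` (±5/10/20/35 on a 0–100
  scale, base 50), or `ghost "<SMILES>"`.
* **statement combinators** — `and if` / `or if` chain clauses, evaluated
  strictly left-to-right with short-circuiting (no precedence levels).
* **loops** —
  `foreach carbon atom offpath defined as c in molecule { ... }`;
  containers are `molecule`, `rings`, or a named set declared with
  `set <name> as <entity> [<where>] in molecule`.
* `//` comments; newlines are whitespace; keywords are case-insensitive.

A product application is retained iff no slot was killed and the final
rating is strictly positive. A multi-slot combination's rating is the
minimum over its slots.

## Pattern extensions

Keying patterns are SMARTS plus two atom-level extensions, applied as
post-filters after RDKit matching:

* `z<n>` — the atom has exactly *n* heteroatom (non-C, non-H) neighbors,
  e.g. `[C;z2:1]`.
* `^e<n>` — *experimental*: the element's valence-electron count (minus
  formal charge) equals *n*.

Matches covering the same atom set are counted once (symmetry
deduplication).

## Transform files

`.slice` (XML) and `.jslice` (JSON) are two lossless serializations of the
same model; `rxnforge convert` maps between them. The element/key set is
defined by this package — see `examples/suzuki_iodo.slice` and
`examples/acylsulfonamide.jslice` for complete annotated instances
(metadata, metrics, SMIRKS + per-slot SMARTS, logic blocks, ghost
templates). Logic is stored as text and parsed at load time, so syntax
errors surface with file context.

Named functional groups (`amine1`, `carboxylic_acid`, `aryl_iodide`, ...)
live in an editable TSV of `name<TAB>SMARTS<TAB>origin_atom_position`
(0-based origin): `src/rxnforge/data/groups.tsv`.

## CLI

```bash
# enumerate a library
rxnforge generate --transform examples/suzuki_iodo.slice \
    --blocks1 examples/aryl_iodides_10.tsv \
    --blocks2 examples/boronic_acids_10.tsv \
    --out-csv products.csv --out-sdf products.sdf

# options: --hide-ghosts --no-kill-low-rated --inchikey-only
#          --dedupe/--no-dedupe --max-products N --workers N
#          --trace trace.jsonl --save-config run.json / --config run.json

# validate a transform, convert dialects, make synthetic block files
rxnforge validate examples/acylsulfonamide.slice
rxnforge convert examples/suzuki_iodo.slice /tmp/suzuki.jslice
rxnforge fixtures --seed 1 --n-per-class 20 \
    --classes aryl_iodide,boronic_acid --out blocks.tsv
```

`generate` prints per-slot compatible-block counts (pattern matching only),
blocks removed by logic, and products written — the two-stage accounting a
screening campaign needs. Runs are deterministic; re-running from a saved
`--config` reproduces byte-identical outputs.

## Library use

```python
from rxnforge import (read_transform, enumerate_products, GenerationOptions)
from rxnforge.io_cli import BlockFileSpec, read_blocks

t = read_transform("examples/suzuki_iodo.slice")
blocks1 = read_blocks(BlockFileSpec("examples/aryl_iodides_10.tsv"))
blocks2 = read_blocks(BlockFileSpec("examples/boronic_acids_10.tsv"))
for record in enumerate_products(t, [blocks1, blocks2], GenerationOptions()):
    print(record.inchikey, record.rating, record.smiles)
```
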