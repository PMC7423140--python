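# Methods

## The data model

A BD5 dataset describes the spatiotemporal dynamics of biological objects
— nuclei, cells, microtubules, whole embryos — as measured by bioimage
informatics pipelines or produced by mechanobiological simulation. The
in-memory document (`bd5tools.model.BD5Document`) mirrors the on-disk
container exactly:

- **scaleUnit** declares the dimensionality (`0D` … `3D+T`) and the linear
  scale factors that map stored coordinates/times to physical units.
  Stored values are kept as recorded; physical x is `x · xScale`, physical
  time is `t · tScale`. With a 2-minute frame interval one stores t = 0, 1,
  2, … under `tScale = 2`, `tUnit = "minute"`; with irregular sampling at
  0, 2 and 7 minutes one stores those values verbatim under `tScale = 1`.
  Equality of t values is exact floating-point comparison — t is a recorded
  value, not a measurement to be clustered; callers quantize upstream if
  their acquisition times carry jitter.
- **objectDef / featureDef** register object classes (oID) and features
  (fID). The oIDs are literally the names of the numbered datasets under
  each time point's `object`/`feature` groups.
- **Time groups** are numbered 0..n−1 by ascending distinct t, so a
  time-ordered sequence survives regardless of interval regularity. Group
  index and stored t are independent by design.
- **Spatial records** hold one table row each. Point, circle and sphere
  entities occupy one row; line and face entities spread an ordered vertex
  list over rows sharing an ID, sequenced by sID = 0..k−1 ("connected from
  the top"). Faces are open rings — the closing segment is implied — and
  vertex order is never canonicalized, because storage order is meaningful.
- **trackInfo** rows are directed (from, to) ID pairs linking objects at an
  earlier time to objects at a later time: continuation (1→1), division
  (1→many), fusion (many→1).

Object IDs are text. The same ID string at two times does *not* imply
identity: identity across time is carried exclusively by trackInfo edges.
Because trackInfo rows carry no time column, an edge endpoint occurring at
several times is resolved latest-for-source / earliest-for-target and
flagged ambiguous; data that gives each object instance a fresh ID per
time point (as the bundled simulator does) is never ambiguous.

## HDF5 dialect

The container layout is `/data` with the three definition tables, optional
`trackInfo`, and one numbered group per time point holding `object/<oID>`
and optional `feature/<oID>` compound datasets (see `bd5tools.store`).
Choices that the format description leaves open, fixed here:

- Numbered groups are unpadded decimal names sorted numerically ("10"
  after "9").
- Column order is fixed per entity kind: ID, t, (sID), x, y, (z),
  (radius), (label). Absent columns are genuinely absent — z exists only
  in 3D files, radius only for circle/sphere, sID only for line/face,
  label only when some row carries one — except in the single-row
  scaleUnit table, which keeps one dtype for every dimensionality and
  stores NaN/empty for absent axes so the linter's dimension check stays
  trivial.
- Numeric payloads are little-endian f8/i8. Record-table strings (ID,
  label, trackInfo endpoints) are **fixed-width UTF-8** sized per dataset.
  This is deliberate: an HDF5 variable-length string costs ~40 bytes of
  heap machinery per value (16-byte descriptor plus a padded global-heap
  object), which roughly doubles the size of coordinate-heavy sphere
  tables and would forfeit the compactness that motivates a binary
  container in the first place. Small metadata tables (definition names,
  unit names) keep variable-length strings; the reader accepts either
  form, so files from writers that chose vlen strings still load.
- Each numbered object dataset carries its entity kind both as a string
  attribute `entity` (self-describing; readers trust it) and as a column
  of objectDef.
- No chunking and no compression filters: decompression cost would tax the
  random access the format exists for, and a contiguous layout keeps one
  time-group read a single sweep.
- Writes are byte-reproducible (HDF5 object timestamps disabled), so
  identical documents give identical files — useful for caching and for
  regression fixtures.

Files from other BD5 writers may differ in these details; the linter
treats unknown datasets/attributes as warnings, not errors, so dialect
extensions degrade gracefully.

## BDML dialect and conversion

The XML side fixes the element vocabulary printed in the format's
structural comparison — `bdml/info/summary/methods/contact`,
`data/scaleUnit/object/feature/component`,
`componentID/componentName/prevID/measurement/objectRef`,
`extFile/bd5File` — and fills the unstated sub-structure conservatively:
measurements nest an entity element (`<sphere>`, `<face>`, …) with
child coordinates, vertices carry an explicit `sID` attribute, and
per-measurement `<property>` elements hold feature values. Unknown
elements are warned about and ignored. Floats are serialized with
`repr()` (shortest exact representation, ≤17 significant digits), so
coordinates survive XML text round trips bit-identically.

Conversion maps componentID→ID, componentName→label, prevID→trackInfo
edge, and buckets components into time groups by distinct time. Divisions
are expressible in plain BDML (two components naming one prevID); a fusion
needs several parents for one component, which the emitter writes as
multiple `prevID` children. Our parser accepts that, so conversion is
lossless in-toolkit, but the conversion report counts such components
because single-prevID consumers cannot represent them. The converter
normalizes row order within a dataset to entity order (all rows of one ID
consecutively) and trackInfo order to component order; documents produced
by this package's builders are already in that normal form.

## Importers

Label-image import uses the raster convention x = column, y = row (z =
slice), 0-based, origin at the top-left pixel center. Point mode takes
each label's pixel-coordinate centroid; face mode traces the outer
boundary of the 4-connected region by Moore-neighbour tracing, clockwise
(image axes, y down) from the topmost-leftmost boundary pixel, stopping
when the walk repeats its first move — deterministic and exactly
invertible by the entity assembler. Regions whose boundary has fewer than
three pixels cannot form a face and are rejected with advice to use point
mode. Multi-page TIFFs map pages to z slices of one time point by default,
or to successive time points on request.

CSV import maps user columns onto record fields, parses numbers strictly
(`float_precision="round_trip"`) and reports the offending 1-based line on
bad cells; export writes every record with 17-significant-digit floats, so
CSV round trips are lossless for all five entity kinds.

## The simulator

`synthcell.simulate` is a minimal branching/coalescing random walk chosen
to exercise every format feature rather than to model biology: spheres
start uniformly in a 100 µm box (n0 = 10, radius 5 µm by default), jitter
by an isotropic Gaussian step (σ = 0.5 µm), divide with per-object
per-step probability p_div = 0.02 into two volume-conserving daughters
(r/2^⅓), and fuse with per-pair per-step probability p_fuse = 0.005 into a
volume-summing product. Note the pair count grows as n²: for populations
far from the default size, p_fuse should be chosen as
2·(wanted fusions per step)/(n(n−1)). Every instance gets a fresh serial
ID each step; continuation, division and fusion all emit trackInfo edges,
and each object carries its volume as feature fID 0. The RNG is numpy's
PCG64, named in the config so fixtures stay stable across releases; a
config (with seed) determines the document bit-for-bit.

What the simulator does *not* emulate: realistic motility or division
statistics, spatial exclusion, segmentation noise, missing detections, ID
reuse across time, or multi-class documents (the structural fuzzer
`random_document` covers the latter two-plus-kinds case for round-trip and
linter testing). Tests passing on synthetic data therefore demonstrate
format, converter and tracker correctness — not robustness to imperfect
real-world tracking output.

## Benchmarks and problem sizes

The benchmark harness serializes the same document both ways and measures
(a) file sizes, (b) the median time to read one time group through an
open BD5 handle, and (c) the median time to parse the whole BDML file —
the access pattern each format affords. Opening a BD5 handle enumerates
group names only; per-group times are read lazily (one element each), so
random access cost is governed by the target group's payload, not by how
many time points the file holds.

Problem sizes used by the test suite and the acceptance script, chosen to
make the comparisons meaningful on one CPU core in minutes: the size
comparison uses a tracked-sphere dataset of ~1500 objects over 70–100
time points (~120k records, BDML ≥ 50 MB), where BD5 comes out ~83%
smaller; the access-scaling check fixes 30 objects per group and grows the
series 10 → 1000 groups, where one-group access stays within measurement
noise of flat while whole-file XML parsing slows by two orders of
magnitude. BD5 is strictly smaller than the equivalent BDML from roughly
100 kB of XML upward; below that the HDF5 container's fixed metadata
(several kB of superblock, group and dtype bookkeeping) dominates and a
sub-kB XML file necessarily wins — a regime the binary format was never
meant for, and excluded from the size-ordering tests.

## Numerical and degenerate-input choices

- Validation returns violations as data (type, key, rule) and never
  raises; writers refuse invalid documents.
- Time groups must hold at least one spatial record (a group's time is
  stored in its rows, so an empty group has no well-defined t).
- Empty-string labels are treated as absent on read; use None, not "".
- `le`-style checks on radii demand strictly positive values.
- Lineage traversal BFS tolerates diamonds (fusions) but aborts on cycles,
  which cannot arise under correct time ordering and signal corrupt input.
- The linter reads dtypes and attributes without loading record arrays
  except where content must be checked (sID runs, radius signs, z
  finiteness), which stream one dataset at a time.

## Known limitations

- No HDF5 external links / multi-file bundles, no compression filters, no
  parallel writes.
- BDML coverage is the fixed v3.0 subset above; files against the full
  official schema parse only insofar as they use these elements (others
  warn).
- Track inference from coordinates is out of scope: trackInfo records
  given links only.
- Face boundaries are single rings; multi-polygon regions and holes are
  not represented.
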