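# Landscape-pattern index formula sheet

All indices are computed on a binary raster: green cells (value 1) form the
class of interest, grouped into **patches by 4-connectivity** (rook
adjacency; configurable to 8 elsewhere, 4 is the package default). The
**landscape** is the full raster.

Notation, with cell side `c` (m):

- `n_i` — cells in patch i; `a_i = n_i c²` — patch area (m²)
- `g_i` — like-adjacencies inside patch i (horizontally or vertically
  adjacent cell pairs, each pair counted once); `g = Σ g_i`
- `p_i = (4 n_i − 2 g_i) c` — patch perimeter (m)
- `A` — total landscape (raster) area (m²); `N` — number of patches
- `n = Σ n_i` — total green cells

1 hm² = 10 000 m².

| Index | Formula | Units |
|---|---|---|
| MESH | `(Σ a_i²) / A` | hm² |
| SPLIT | `A² / Σ a_i²` | — |
| DIVISION | `1 − Σ (a_i/A)²` | 0–1 |
| PD | `N / A × 100` | patches / 100 hm² |
| LPI | `max a_i / A × 100` | % |
| AREA_AM | `Σ a_i² / Σ a_i` | hm² |
| SHAPE_MN | `mean_i( 0.25 p_i / √a_i )` | ≥ 1 |
| LSI | `0.25 Σ p_i / √A` | ≥ simple-shape baseline |
| AI | `100 · g / g_max` | % |

`g_max` is the like-adjacency count of the most compact arrangement of `n`
cells: with `m = ⌊√n⌋`,

- `g_max = 2m(m−1)` if `m² = n`
- `g_max = 2m(m−1) + 2(n−m²) − 1` if `n ≤ m(m+1)`
- `g_max = 2m(m−1) + 2(n−m²) − 2` otherwise.

Conventions:

- A single green cell admits no adjacency (`g_max = 0`); AI is defined as 0
  with a warning.
- A raster with no green cell is an error (a park must contain at least one
  green patch).
- SHAPE and LSI use the perimeter-based shape formula `0.25 p / √a`, which
  equals 1 for a square patch; the square, not the raster-cell aggregate, is
  the compactness baseline.

Closed forms used as checks: a single patch covering the entire (square)
raster gives LPI = 100, DIVISION = 0, SPLIT = 1, MESH = A, AI = 100; a
perfect checkerboard has no like-adjacency, so AI = 0.

Direction when standardizing across parks: AI, LPI, MESH are positive
(larger = less fragmented = better); PD, LSI, AREA_AM, SHAPE_MN, DIVISION,
SPLIT are negative.
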