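# The molecular-graph JSON dialect

`molcolor.to_json` / `molcolor.from_json` convert between `MolecularGraph`
and a small JSON object.  The serialization is canonical: atoms are listed by
ascending index and bonds by ascending endpoint pair, so two structurally
identical graphs produce identical documents regardless of construction
order (endpoint *direction* inside a bond record is preserved, because it is
semantic for wedge bonds).

## Top level

| key         | type   | notes                                    |
|-------------|--------|------------------------------------------|
| `source_id` | string | originating compound id; may be empty    |
| `atoms`     | array  | required                                 |
| `bonds`     | array  | required                                 |

## Atom records

| key             | type    | default | notes                                         |
|-----------------|---------|---------|-----------------------------------------------|
| `index`         | integer | —       | required, unique, 0-based                     |
| `element`       | string  | —       | required; periodic symbol or R-group token (`R`, `R#`, `*`, `X`) |
| `charge`        | integer | 0       | formal charge in elementary units             |
| `stereo_parity` | integer | 0       | molfile atom-block stereo code                |
| `mass_delta`    | integer | 0       | isotope offset, molfile convention            |
| `x`, `y`, `z`   | number  | 0.0     | coordinates (molfile units)                   |
| `is_aromatic`   | boolean | false   | set by aromatic perception                    |

## Bond records

| key         | type           | default | notes                                   |
|-------------|----------------|---------|-----------------------------------------|
| `a`, `b`    | integer        | —       | required atom indices, `a != b`         |
| `order`     | integer        | 1       | 1, 2, 3, or 4 (= aromatic)              |
| `wedge`     | integer        | 0       | molfile bond-block stereo code          |
| `cis_trans` | string or null | null    | `"cis"` / `"trans"`, set by perception  |

Validation errors (missing keys, wrong types, bonds referencing unknown
atoms, duplicate bonds) raise `JsonSchemaError` with the offending location.
Round trip: `from_json(to_json(g))` reproduces `g` field for field.
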