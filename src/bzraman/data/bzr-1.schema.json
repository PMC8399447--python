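{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "bzr-1 conformer-ensemble interchange format",
  "description": "One JSON file per peptide-fragment ensemble. Units: coordinates in angstrom, energies in kcal/mol relative to the ensemble minimum, frequencies in unscaled harmonic cm-1, Raman activities in A^4/amu, charge transfer and electron densities in electrons. Atom indices are 0-based; residues are numbered 1-based from the alpha-NH3+ terminus.",
  "type": "object",
  "required": ["schema", "fragment", "conformers"],
  "properties": {
    "schema": {"const": "bzr-1"},
    "fragment": {"type": "string"},
    "temperature": {"type": "number", "exclusiveMinimum": 0, "default": 298.0},
    "conformers": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "sequence", "relative_energy"],
        "properties": {
          "id": {"type": "string"},
          "sequence": {"type": "string", "pattern": "^[ADEG]+$"},
          "relative_energy": {"type": "number", "minimum": 0},
          "protonated_terminus": {"type": "boolean", "default": false},
          "atoms": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["element", "position"],
              "properties": {
                "element": {"type": "string"},
                "position": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
                "natural_electron_density": {"type": "number", "minimum": 0}
              }
            }
          },
          "modes": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["frequency", "raman_activity", "displacements"],
              "properties": {
                "frequency": {"type": "number", "exclusiveMinimum": 0},
                "raman_activity": {"type": "number", "minimum": 0},
                "displacements": {
                  "type": "array",
                  "items": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3}
                }
              }
            }
          },
          "hbonds": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["donor", "hydrogen", "acceptor"],
              "properties": {
                "donor": {"type": "integer", "minimum": 0},
                "hydrogen": {"type": "integer", "minimum": 0},
                "acceptor": {"type": "integer", "minimum": 0},
                "delta_q": {"type": "number", "minimum": 0}
              }
            }
          },
          "backbone_map": {
            "type": "object",
            "required": ["residues", "nterm_n", "cterm_c", "cterm_o1", "cterm_o2"],
            "properties": {
              "residues": {
                "type": "array",
                "items": {
                  "type": "object",
                  "required": ["n", "ca", "c", "o"],
                  "properties": {
                    "n": {"type": "integer"},
                    "ca": {"type": "integer"},
                    "c": {"type": "integer"},
                    "o": {"type": "integer"},
                    "cb": {"type": "integer"}
                  }
                }
              },
              "nterm_n": {"type": "integer"},
              "cterm_c": {"type": "integer"},
              "cterm_o1": {"type": "integer"},
              "cterm_o2": {"type": "integer"}
            }
          }
        }
      }
    }
  }
}
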