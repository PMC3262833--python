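{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "strokeclass cohort CSV row",
  "description": "One patient of a stroke cohort table. The file is comma-separated UTF-8 with a mandatory header naming every property below; list-valued cells join their tokens with ';' and missing values are empty strings.",
  "type": "object",
  "required": [
    "patient_id", "age", "sex", "nihss_admission", "diabetes", "cad",
    "atrial_fibrillation", "smoking", "hyperlipidemia", "hypertension",
    "iv_tpa", "ia_therapy", "occlusion_sites", "anterior_hypodense_regions",
    "bilateral_pons_hypodensity", "bilateral_thalamus_hypodensity", "mrs_6mo"
  ],
  "properties": {
    "patient_id": {"type": "string", "minLength": 1, "description": "Opaque unique identifier."},
    "age": {"type": "number", "exclusiveMinimum": 0, "description": "Age in years."},
    "sex": {"enum": ["male", "female"]},
    "nihss_admission": {
      "type": ["integer", "null"], "minimum": 0, "maximum": 42,
      "description": "Admission NIHSS; empty cell when not reliably obtained."
    },
    "diabetes": {"enum": [0, 1]},
    "cad": {"enum": [0, 1]},
    "atrial_fibrillation": {"enum": [0, 1]},
    "smoking": {"enum": [0, 1]},
    "hyperlipidemia": {"enum": [0, 1]},
    "hypertension": {"enum": [0, 1]},
    "iv_tpa": {"enum": [0, 1], "description": "Received intravenous tPA."},
    "ia_therapy": {"enum": [0, 1], "description": "Received intra-arterial (endovascular) therapy."},
    "occlusion_sites": {
      "type": "string",
      "description": "';'-joined subset of DISTAL_ICA, MCA_M1, MCA_M2, BASILAR, OTHER (CTA occlusions)."
    },
    "anterior_hypodense_regions": {
      "type": "string",
      "description": "';'-joined subset of the 10 ASPECTS regions C, L, IC, I, M1c..M6c (NCCT hypodensities)."
    },
    "bilateral_pons_hypodensity": {"enum": [0, 1]},
    "bilateral_thalamus_hypodensity": {"enum": [0, 1]},
    "mrs_6mo": {
      "type": ["integer", "null"], "minimum": 0, "maximum": 6,
      "description": "6-month modified Rankin scale; empty cell when not reliably obtained. mRS > 2 defines poor outcome; 6 (death) is a valid value."
    }
  }
}
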