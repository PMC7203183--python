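# Annotation catalogue for the 25 theoretical minimal RNA rings.
#
# Only ring 25 (named AB) has its sequence published in the source tables the
# fixtures transcribe; it is stored in the rotation that defines splicing
# position 1 (the rotation with highest homology to an ancestral tRNA), so
# anchor_offset is 0 relative to the stored string.  Cognate amino acids are
# known only for ring 25 (Gly, written G) and ring 2 (Sec, the UGA-read
# selenocysteine).  Genetic-code integration orders are not published at this
# granularity and require curation from the cited amino-acid chronology; they
# ship as null and are user-editable.
rings:
  - {ring_id: 1,  name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 2,  name: null, sequence: null, cognate_aa: Sec,  integration_order: null, anchor_offset: null}
  - {ring_id: 3,  name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 4,  name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 5,  name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 6,  name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 7,  name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 8,  name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 9,  name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 10, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 11, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 12, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 13, name: AL,   sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 14, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 15, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 16, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 17, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 18, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 19, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 20, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 21, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 22, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 23, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 24, name: null, sequence: null, cognate_aa: null, integration_order: null, anchor_offset: null}
  - {ring_id: 25, name: AB,   sequence: UAUGAAUGGUGCCAUUCAAGAC, cognate_aa: G, integration_order: null, anchor_offset: 0}
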