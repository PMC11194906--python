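expert_id,familiarity,practical_experience,theoretical_analysis,peer_knowledge,intuition
E01,very_familiar,high,high,high,high
E02,very_familiar,high,high,high,high
E03,very_familiar,high,high,high,high
E04,very_familiar,high,high,high,high
E05,very_familiar,high,high,high,high
E06,very_familiar,high,high,high,high
E07,very_familiar,high,high,high,high
E08,relatively_familiar,high,high,high,high
E09,relatively_familiar,high,high,high,high
E10,relatively_familiar,high,high,high,high
E11,relatively_familiar,high,low,low,low
E12,relatively_familiar,high,low,low,low
E13,relatively_familiar,high,low,low,low
E14,relatively_familiar,high,low,low,low
E15,relatively_familiar,low,low,low,low
E16,relatively_familiar,low,low,low,low
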