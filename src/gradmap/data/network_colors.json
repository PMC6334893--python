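{
  "1": {"name": "visual", "color": "#4b0082"},
  "2": {"name": "somatomotor", "color": "#1f6fd6"},
  "3": {"name": "dorsal attention", "color": "#2e8b57"},
  "4": {"name": "ventral attention", "color": "#9b59b6"},
  "5": {"name": "limbic", "color": "#f5f5dc"},
  "6": {"name": "frontoparietal", "color": "#e67e22"},
  "7": {"name": "default mode", "color": "#d62728"}
}
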