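no adverse event
off label use
product quality issue
expired product administered
product dose omission
drug prescribing error
product substitution issue
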