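# Hierarchical language-module specification.
#
# Level-1 modules are defined per hemisphere from Brodmann areas (BA), with
# BA21/BA22 split into anterior/posterior parts at the median y coordinate.
# Higher levels are unions of Level-1 modules; "Semantic processing" feeds
# both "Word processing" and "Language sensory", so Level-2 membership is a
# set. Level 3 collects each hemisphere's language system; Level 4 is both.
name: language
language_bas: [20, 21, 22, 38, 39, 40, 41, 42, 44, 45, 47]
split_bas: [21, 22]
levels:
  1:
    - name: Word recognition
      hemisphere: each
      members: ["BA20", "BA21:post", "BA22:post"]
    - name: Semantic processing
      hemisphere: each
      members: ["BA38", "BA21:ant", "BA22:ant"]
    - name: Syntactic processing
      hemisphere: each
      members: ["BA39", "BA40"]
    - name: Auditory processing
      hemisphere: each
      members: ["BA41", "BA42"]
    - name: Motoric language
      hemisphere: each
      members: ["BA44", "BA45", "BA47"]
  2:
    - name: Word processing
      hemisphere: each
      level1: ["Word recognition", "Semantic processing"]
    - name: Language sensory
      hemisphere: each
      level1: ["Semantic processing", "Auditory processing"]
    - name: Language motor
      hemisphere: each
      level1: ["Motoric language"]
  3:
    - name: Language network
      hemisphere: each
      level1: ["Word recognition", "Semantic processing", "Syntactic processing",
               "Auditory processing", "Motoric language"]
  4:
    - name: Language network
      hemisphere: both
      level1: ["Word recognition", "Semantic processing", "Syntactic processing",
               "Auditory processing", "Motoric language"]
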