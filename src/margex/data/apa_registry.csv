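raw_name,canonical_name,disciplines,core_only
Journal of Personality and Social Psychology,Journal of Personality and Social Psychology,social,false
Developmental Psychology,Developmental Psychology,developmental,false
Journal of Experimental Psychology: General,Journal of Experimental Psychology: General,experimental;cognitive,false
Journal of Experimental Psychology General,Journal of Experimental Psychology: General,experimental;cognitive,false
Journal of Abnormal Psychology,Journal of Abnormal Psychology,clinical,false
Journal of Consulting and Clinical Psychology,Journal of Consulting and Clinical Psychology,clinical,false
Journal of Educational Psychology,Journal of Educational Psychology,educational,false
Law and Human Behavior,Law and Human Behavior,forensic,false
Health Psychology,Health Psychology,health,false
Journal of Applied Psychology,Journal of Applied Psychology,organizational,false
Journal of Comparative Psychology,Journal of Comparative Psychology,experimental,false
Journal of Comparative and Physiological Psychology,Journal of Comparative Psychology,experimental,false
Psychology and Aging,Psychology and Aging,developmental,false
Emotion,Emotion,social;experimental,false
Neuropsychology,Neuropsychology,cognitive,false
American Psychologist,American Psychologist,,true
Review of General Psychology,Review of General Psychology,,true
Psychological Bulletin,Psychological Bulletin,,true
Psychological Review,Psychological Review,,true
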