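# Default evaluation indicator system: 9 first-level dimensions (X1..X9),
# each with three binary second-level criteria, for medical-quality
# intelligent-management policy (MQIMP) evaluation.
dimensions:
  - code: X1
    name: Policy objectives
    secondaries:
      - code: X1-1
        name: Clarity of objectives
        criterion: Whether the specific scenarios of intelligent management and control are clearly defined
      - code: X1-2
        name: Hierarchy of objectives
        criterion: Whether the objectives are distinguished
      - code: X1-3
        name: Forward-looking of objectives
        criterion: Whether it matches the time nodes of long-term plans
  - code: X2
    name: Policy entities
    secondaries:
      - code: X2-1
        name: Coverage of entities
        criterion: Whether it includes core departments such as health, medical security, and development and reform commissions
      - code: X2-2
        name: Clarity of responsibilities
        criterion: Whether the roles of each entity in intelligent management and control are clarified
      - code: X2-3
        name: Collaboration mechanism
        criterion: Whether collaborative measures such as cross-departmental data sharing and joint law enforcement are mentioned
  - code: X3
    name: Intelligent technology application
    secondaries:
      - code: X3-1
        name: Coverage of technology types
        criterion: Whether the specific applications of technologies such as big data, artificial intelligence, and blockchain are clarified
      - code: X3-2
        name: Focus on application scenarios
        criterion: Whether it covers the whole process of pre-event early warning, in-event intervention, and post-event evaluation
      - code: X3-3
        name: Technical standards and specifications
        criterion: Whether application standards for intelligent technologies are formulated
  - code: X4
    name: Medical quality control dimension
    secondaries:
      - code: X4-1
        name: Clinical quality management and control
        criterion: Whether it includes professional quality control indicators
      - code: X4-2
        name: Medical security fund management and control
        criterion: Whether intelligent fund review and monitoring rules are clarified
      - code: X4-3
        name: Data quality management and control
        criterion: Whether the standards, security and quality of health care data are mentioned
  - code: X5
    name: Control measures
    secondaries:
      - code: X5-1
        name: Mandatory measures
        criterion: Whether it includes binding means such as laws, regulations, standards and assessments
      - code: X5-2
        name: Incentive measures
        criterion: Whether incentive means such as financial support and pilot demonstrations are mentioned
      - code: X5-3
        name: Innovative measures
        criterion: Whether new management and control methods are introduced
  - code: X6
    name: Data support
    secondaries:
      - code: X6-1
        name: Data platform construction
        criterion: Whether the construction requirements for data platforms at all levels are clarified
      - code: X6-2
        name: Data sharing mechanism
        criterion: Whether the scope and process of cross-institutional and cross-regional data sharing are specified
      - code: X6-3
        name: Data security assurance
        criterion: Whether measures such as data encryption, privacy protection and security review are included
  - code: X7
    name: Implementation guarantee
    secondaries:
      - code: X7-1
        name: Resource assurance
        criterion: Whether resource support such as funds, talents and technologies is mentioned
      - code: X7-2
        name: Supervision mechanism
        criterion: Whether the supervision entity and assessment method for policy implementation are clarified
      - code: X7-3
        name: Responsibility investigation
        criterion: Whether measures for investigating responsibilities for failure to implement policies are specified
  - code: X8
    name: Policy audience
    secondaries:
      - code: X8-1
        name: Coverage of audience
        criterion: Whether it includes medical institutions at all levels
      - code: X8-2
        name: Targeting of audience
        criterion: Whether differentiated requirements are formulated for different audiences
      - code: X8-3
        name: Guidance for audience
        criterion: Whether guidance measures such as training and publicity for the audience are included
  - code: X9
    name: Policy timeliness
    secondaries:
      - code: X9-1
        name: Implementation cycle
        criterion: Whether the start and end time or phase division of policy implementation is clarified
      - code: X9-2
        name: Update frequency
        criterion: Whether the dynamic adjustment mechanism of the policy is mentioned
      - code: X9-3
        name: Timeliness matching
        criterion: Whether the policy content matches the development of technology
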